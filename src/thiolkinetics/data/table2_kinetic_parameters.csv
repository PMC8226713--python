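treatment,heat_state,k0,ea,r2
control,raw,1.2e7,33.05,0.941
control,cooked,7.98e8,42.49,0.998
allspice,raw,1.66e20,105.63,0.905
allspice,cooked,8.94e9,48.9,0.899
basil,raw,2.46e10,51.1,0.998
basil,cooked,4.92e9,47.6,0.979
bay_leaf,raw,3.09e12,63.75,0.977
bay_leaf,cooked,3.37e16,85.13,0.985
black_seed,raw,6.34e13,70.5,0.989
black_seed,cooked,6.06e11,58.77,0.950
caraway,raw,1.19e22,116.1,0.963
caraway,cooked,3.34e17,92.00,0.981
cardamom,raw,8.15e18,97.97,0.970
cardamom,cooked,3.85e9,46.63,0.996
clove,raw,2.18e17,90.47,0.963
clove,cooked,3.51e12,63.58,0.979
garlic,raw,1.65e9,45.12,0.882
garlic,cooked,4.19e5,25.01,0.926
nutmeg,raw,3.49e17,90.86,0.914
nutmeg,cooked,4.2e15,80.68,0.998
onion,raw,1.55e8,39.2,0.870
onion,cooked,5.09e7,37.34,0.934
oregano,raw,1.04e9,43.72,0.961
oregano,cooked,1.49e9,44.52,0.995
rosemary,raw,1.8e10,50.87,0.988
rosemary,cooked,1.17e10,49.22,0.991
thyme,raw,2.76e13,68.36,0.996
thyme,cooked,1.67e8,38.99,0.945
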