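label,x,y,z
E1,-1.354,7.467,4.839
E2,-2.661,7.467,4.262
E3,-3.969,7.467,3.082
E4,-1.554,6.4,6.134
E5,-3.261,6.4,5.423
E6,-4.968,6.4,3.919
E7,-2.192,5.333,6.91
E8,-5.177,5.333,5.075
E9,1.354,7.467,4.839
E10,2.661,7.467,4.262
E11,3.969,7.467,3.082
E12,1.554,6.4,6.134
E13,3.261,6.4,5.423
E14,4.968,6.4,3.919
E15,1.695,5.333,7.049
E16,3.685,5.333,6.243
E17,5.675,5.333,4.512
E18,-1.556,3.7,8.055
E19,-3.268,3.7,7.525
E20,-4.98,3.7,6.52
E21,-6.692,3.7,4.746
E22,-1.9,2.7,8.373
E23,-4.299,2.7,7.431
E24,-6.699,2.7,5.37
E25,-1.938,1.7,8.623
E26,-4.415,1.7,7.656
E27,-6.892,1.7,5.532
E28,1.556,3.7,8.055
E29,3.268,3.7,7.525
E30,4.98,3.7,6.52
E31,6.692,3.7,4.746
E32,1.6,2.7,8.435
E33,3.399,2.7,7.884
E34,5.199,2.7,6.832
E35,6.999,2.7,4.973
E36,1.938,1.7,8.623
E37,4.415,1.7,7.656
E38,6.892,1.7,5.532
E39,-1.458,0.075,8.881
E40,-2.974,0.075,8.494
E41,-4.49,0.075,7.8
E42,-6.006,0.075,6.703
E43,-7.522,0.075,4.941
E44,-1.641,-0.975,8.795
E45,-3.524,-0.975,8.224
E46,-5.407,-0.975,7.128
E47,-7.29,-0.975,5.187
E48,-1.621,-2.025,8.618
E49,-3.463,-2.025,8.057
E50,-5.305,-2.025,6.983
E51,-7.147,-2.025,5.082
E52,-1.585,-3.075,8.309
E53,-3.356,-3.075,7.764
E54,-5.126,-3.075,6.728
E55,-6.897,-3.075,4.897
E56,1.458,0.075,8.881
E57,2.974,0.075,8.494
E58,4.49,0.075,7.8
E59,6.006,0.075,6.703
E60,7.522,0.075,4.941
E61,1.641,-0.975,8.795
E62,3.524,-0.975,8.224
E63,5.407,-0.975,7.128
E64,7.29,-0.975,5.187
E65,1.621,-2.025,8.618
E66,3.463,-2.025,8.057
E67,5.305,-2.025,6.983
E68,7.147,-2.025,5.082
E69,1.585,-3.075,8.309
E70,3.356,-3.075,7.764
E71,5.126,-3.075,6.728
E72,6.897,-3.075,4.897
E73,-1.486,-4.833,7.445
E74,-3.057,-4.833,6.949
E75,-4.628,-4.833,6.018
E76,-6.199,-4.833,4.383
E77,-1.598,-6.1,6.422
E78,-3.394,-6.1,5.681
E79,-5.19,-6.1,4.105
E80,-1.376,-7.367,4.984
E81,-2.728,-7.367,4.392
E82,-4.081,-7.367,3.175
E83,1.486,-4.833,7.445
E84,3.057,-4.833,6.949
E85,4.628,-4.833,6.018
E86,6.199,-4.833,4.383
E87,1.598,-6.1,6.422
E88,3.394,-6.1,5.681
E89,5.19,-6.1,4.105
E90,1.376,-7.367,4.984
E91,2.728,-7.367,4.392
E92,4.081,-7.367,3.175
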