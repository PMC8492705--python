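label,group
E1,Anterior L
E2,Anterior L
E3,Anterior L
E4,Anterior L
E5,Anterior L
E6,Anterior L
E7,Anterior L
E8,Anterior L
E9,Anterior R
E10,Anterior R
E11,Anterior R
E12,Anterior R
E13,Anterior R
E14,Anterior R
E15,Anterior R
E16,Anterior R
E17,Anterior R
E18,Posterior L
E19,Posterior L
E20,Posterior L
E21,Posterior L
E22,Posterior L
E23,Posterior L
E24,Posterior L
E25,Posterior L
E26,Posterior L
E27,Posterior L
E28,Posterior R
E29,Posterior R
E30,Posterior R
E31,Posterior R
E32,Posterior R
E33,Posterior R
E34,Posterior R
E35,Posterior R
E36,Posterior R
E37,Posterior R
E38,Posterior R
E39,Parietal L
E40,Parietal L
E41,Parietal L
E42,Parietal L
E43,Parietal L
E44,Parietal L
E45,Parietal L
E46,Parietal L
E47,Parietal L
E48,Parietal L
E49,Parietal L
E50,Parietal L
E51,Parietal L
E52,Parietal L
E53,Parietal L
E54,Parietal L
E55,Parietal L
E56,Parietal R
E57,Parietal R
E58,Parietal R
E59,Parietal R
E60,Parietal R
E61,Parietal R
E62,Parietal R
E63,Parietal R
E64,Parietal R
E65,Parietal R
E66,Parietal R
E67,Parietal R
E68,Parietal R
E69,Parietal R
E70,Parietal R
E71,Parietal R
E72,Parietal R
E73,Occipital L
E74,Occipital L
E75,Occipital L
E76,Occipital L
E77,Occipital L
E78,Occipital L
E79,Occipital L
E80,Occipital L
E81,Occipital L
E82,Occipital L
E83,Occipital R
E84,Occipital R
E85,Occipital R
E86,Occipital R
E87,Occipital R
E88,Occipital R
E89,Occipital R
E90,Occipital R
E91,Occipital R
E92,Occipital R
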