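label,f1_mean,f1_sd,f2_mean,f2_sd
human_male_u,307.36,50.01,875.97,155.46
human_female_u,377.86,46.76,960.57,171.46
human_child_u,432.37,87.48,1193.33,274.61
chimp_hoo,374.44,67.02,896.25,133.04
chimp_hoo_methods,358.75,56.93,896.25,133.04
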