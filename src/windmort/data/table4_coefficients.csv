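year,model,n_nights,alpha0,alpha1,alpha2,alpha3,mortality_model,mortality_model_lwr,mortality_model_upr,corrected_count,corrected_lwr,corrected_upr
2007,one_level,473,-2.7,0.4,-0.2,-0.2,37,28,49,38,27,59
2007,three_level,473,-2.3,0.5,0.4,-0.7,38,29,49,38,27,59
2008,one_level,1225,-3.5,0.4,-1.8,-0.8,56,46,70,57,42,89
2008,three_level,1225,-4.1,0.5,-2.9,-1.3,57,46,71,57,42,89
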