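year,n_turbines,n_nights,n_recordings,n_carcasses,mean_detection,wind_mean,wind_sd
2007,12,473,2187,22,0.58,5.2,1.9
2008,18,1225,16263,35,0.61,5.5,1.8
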