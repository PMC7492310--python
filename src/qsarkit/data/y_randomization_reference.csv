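model,R,R2,Q2
original,0.860062,0.739706,0.554712
random_1,0.569068,0.323839,-1.17969
random_2,0.556022,0.309161,-0.34937
random_3,0.427541,0.182791,-0.53108
random_4,0.501596,0.251598,-0.85524
random_5,0.645348,0.416475,0.063014
random_6,0.502871,0.252879,-0.52581
random_7,0.522143,0.272633,-0.24368
random_8,0.595235,0.354305,-1.92796
random_9,0.423402,0.179269,-0.35291
random_10,0.588755,0.346633,-0.06237
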