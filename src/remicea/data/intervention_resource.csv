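phase,year,sachets_mean,sachets_sd,visits_mean,visits_sd
total_diet_replacement,1,388.4,153.8,7.8,2.8
food_reintroduction,1,62.6,49.1,3.6,1.8
weight_loss_management,1,34.3,53.0,4.1,3.0
weight_loss_management,2,55.8,91.9,6.6,5.2
weight_loss_management,3,24.9,53.4,2.1,2.1
weight_loss_management,4,17.4,47.1,1.8,2.0
weight_loss_management,5,11.9,36.2,1.2,1.4
rescue,1,24.4,49.8,0.8,1.6
rescue,2,40.0,66.3,1.3,2.2
rescue,3,19.4,44.7,0.5,1.1
rescue,4,26.6,57.6,0.7,1.4
rescue,5,16.1,47.2,0.5,1.1
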