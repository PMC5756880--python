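species_role,kind,population,locus,detail,value
host,config,theta_divergence,,,0.1
host,selfing_F,X,,,0.0
host,selfing_F,Y,,,0.0
host,null_rate,,locus1,,0.1
host,null_rate,,locus2,,0.1
host,pop_freq,X,locus1,451,0.0
host,pop_freq,X,locus1,453,1.0
host,pop_freq,X,locus2,263,0.999992239373948
host,pop_freq,X,locus2,265,7.760626052048326e-06
host,pop_freq,Y,locus1,451,0.0
host,pop_freq,Y,locus1,453,1.0
host,pop_freq,Y,locus2,263,0.9999988409430037
host,pop_freq,Y,locus2,265,1.1590569962483402e-06
host,clone,X,X-3,X-2,1.0
parasitoid,config,theta_divergence,,,0.05
parasitoid,selfing_F,X,,,0.0
parasitoid,selfing_F,Y,,,0.0
parasitoid,null_rate,,locus1,,0.0
parasitoid,null_rate,,locus2,,0.0
parasitoid,hotspot,Y,locus1,,0.8
parasitoid,pop_freq,X,locus1,126,0.9975289221631476
parasitoid,pop_freq,X,locus1,128,0.0024710778368525017
parasitoid,pop_freq,X,locus2,892,0.9998902734846404
parasitoid,pop_freq,X,locus2,894,0.00010972651535957241
parasitoid,pop_freq,Y,locus1,126,0.1984707919006478
parasitoid,pop_freq,Y,locus1,128,0.8015292080993521
parasitoid,pop_freq,Y,locus2,892,0.9835298518775425
parasitoid,pop_freq,Y,locus2,894,0.016470148122457545
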