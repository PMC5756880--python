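species_role,kind,population,locus,detail,value
host,config,theta_divergence,,,0.1
host,selfing_F,X,,,0.0
host,selfing_F,Y,,,0.0
host,null_rate,,locus1,,0.1
host,null_rate,,locus2,,0.1
host,pop_freq,X,locus1,117,0.8436936767938815
host,pop_freq,X,locus1,119,0.15630632320611848
host,pop_freq,X,locus2,323,0.9999999963722265
host,pop_freq,X,locus2,325,3.627773526079706e-09
host,pop_freq,Y,locus1,117,0.3962801668331755
host,pop_freq,Y,locus1,119,0.6037198331668244
host,pop_freq,Y,locus2,323,0.9982093802669977
host,pop_freq,Y,locus2,325,0.0017906197330023012
parasitoid,config,theta_divergence,,,0.05
parasitoid,selfing_F,X,,,0.0
parasitoid,selfing_F,Y,,,0.0
parasitoid,null_rate,,locus1,,0.0
parasitoid,null_rate,,locus2,,0.0
parasitoid,hotspot,Y,locus1,,0.8
parasitoid,pop_freq,X,locus1,251,0.05530369584145388
parasitoid,pop_freq,X,locus1,253,0.944696304158546
parasitoid,pop_freq,X,locus2,415,0.9994161518731647
parasitoid,pop_freq,X,locus2,417,0.0005838481268351983
parasitoid,pop_freq,Y,locus1,251,0.8073460972267409
parasitoid,pop_freq,Y,locus1,253,0.19265390277325917
parasitoid,pop_freq,Y,locus2,415,0.9998511489959113
parasitoid,pop_freq,Y,locus2,417,0.0001488510040886
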