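species_role,kind,population,locus,detail,value
host,config,theta_divergence,,,0.1
host,selfing_F,X,,,0.0
host,selfing_F,Y,,,0.0
host,null_rate,,locus1,,0.1
host,null_rate,,locus2,,0.1
host,pop_freq,X,locus1,195,1.0
host,pop_freq,X,locus1,197,5.611386788651565e-36
host,pop_freq,X,locus2,100,1.034440311534157e-12
host,pop_freq,X,locus2,102,0.9999999999989656
host,pop_freq,Y,locus1,195,1.0
host,pop_freq,Y,locus1,197,2.2350987004350754e-27
host,pop_freq,Y,locus2,100,8.580721799322614e-24
host,pop_freq,Y,locus2,102,1.0
host,clone,X,X-2,X-1,1.0
host,clone,X,X-3,X-1,1.0
parasitoid,config,theta_divergence,,,0.05
parasitoid,selfing_F,X,,,0.0
parasitoid,selfing_F,Y,,,0.0
parasitoid,null_rate,,locus1,,0.0
parasitoid,null_rate,,locus2,,0.0
parasitoid,hotspot,Y,locus1,,0.8
parasitoid,pop_freq,X,locus1,741,0.3022394165716905
parasitoid,pop_freq,X,locus1,743,0.6977605834283094
parasitoid,pop_freq,X,locus2,811,0.227691863810734
parasitoid,pop_freq,X,locus2,813,0.772308136189266
parasitoid,pop_freq,Y,locus1,741,0.8760055016514889
parasitoid,pop_freq,Y,locus1,743,0.123994498348511
parasitoid,pop_freq,Y,locus2,811,0.49886408585471437
parasitoid,pop_freq,Y,locus2,813,0.5011359141452857
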