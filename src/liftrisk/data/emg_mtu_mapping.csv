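# Mapping between the six bilateral surface-EMG channels (plus the unmeasured
# "passive" pool) and the muscle-tendon units of the full lifting trunk model
# they drive. n_units counts MTUs across both sides; the total is 238.
semg_channel,mtu_row,n_units
erector_spinae_longissimus,longissimus_thoracis_pars_lumborum,10
erector_spinae_longissimus,longissimus_thoracis_pars_thoracis,8
erector_spinae_iliocostalis,iliocostalis_lumborum_pars_lumborum,42
erector_spinae_iliocostalis,iliocostalis_lumborum_pars_thoracis,16
rectus_abdominis_middle,rectus_abdominis,2
rectus_abdominis_middle,external_oblique,12
rectus_abdominis_middle,internal_oblique,12
passive,quadratus_lumborum,36
passive,psoas_major,22
passive,multifidus,50
passive,latissimus_dorsi,28
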