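period,determination,n_records,id_eagle,id_noneagle
original_configuration,eagle,4369,3975,394
original_configuration,non-eagle,62562,9362,53200
original_configuration,no-image,0,0,0
system_update,eagle,3110,2134,976
system_update,non-eagle,40025,1715,38310
system_update,no-image,182,82,100
equipment_issue,eagle,16725,10925,5800
equipment_issue,non-eagle,161710,14000,147710
equipment_issue,no-image,517,158,359
equipment_replacement,eagle,16861,14158,2703
equipment_replacement,non-eagle,152894,35090,117804
equipment_replacement,no-image,410,306,104
neural_network_upgrade,eagle,3260,2932,328
neural_network_upgrade,non-eagle,148890,23619,125271
neural_network_upgrade,no-image,22,4,18
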