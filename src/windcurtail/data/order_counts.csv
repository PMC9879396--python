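period,target_class,distance_class,n_orders
original_configuration,eagle,far,116
original_configuration,eagle,near,12
original_configuration,eagle,within,1
system_update,eagle,far,47
system_update,eagle,near,10
system_update,eagle,within,1
equipment_issue,eagle,far,318
equipment_issue,eagle,near,40
equipment_issue,eagle,within,10
equipment_replacement,eagle,far,217
equipment_replacement,eagle,near,10
equipment_replacement,eagle,within,1
neural_network_upgrade,eagle,far,66
neural_network_upgrade,eagle,near,1
neural_network_upgrade,eagle,within,0
original_configuration,non-eagle,far,235
original_configuration,non-eagle,near,74
original_configuration,non-eagle,within,22
system_update,non-eagle,far,87
system_update,non-eagle,near,66
system_update,non-eagle,within,18
equipment_issue,non-eagle,far,931
equipment_issue,non-eagle,near,413
equipment_issue,non-eagle,within,112
equipment_replacement,non-eagle,far,1045
equipment_replacement,non-eagle,near,240
equipment_replacement,non-eagle,within,59
neural_network_upgrade,non-eagle,far,1462
neural_network_upgrade,non-eagle,near,588
neural_network_upgrade,non-eagle,within,87
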