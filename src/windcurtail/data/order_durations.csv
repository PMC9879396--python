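target_class,n_orders,total_duration_h
eagle,850,53.6
non-eagle,5439,301.3
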