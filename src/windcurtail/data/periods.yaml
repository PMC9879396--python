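- name: original_configuration
  start: "2018-06-21"
  end: "2018-08-31"
  excluded: []
- name: system_update
  start: "2018-09-08"
  end: "2018-10-19"
  excluded: []
- name: equipment_issue
  start: "2018-10-20"
  end: "2019-02-26"
  excluded: []
- name: equipment_replacement
  start: "2019-02-27"
  end: "2019-04-25"
  excluded:
    - ["2019-04-02", "2019-04-19"]
- name: neural_network_upgrade
  start: "2019-04-26"
  end: "2019-06-20"
  excluded: []
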