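region,goal_gw,low_impact_gw
Alberta,4.11,91
Montana,5.26,139
Nebraska,7.88,163
North Dakota,2.26,254
Saskatchewan,1.10,137
South Dakota,8.06,238
Wyoming,1.28,34
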