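region,status,n_turbines,n_low_impact
Alberta,existing,312,73
Montana,existing,264,128
Nebraska,existing,148,52
North Dakota,existing,885,392
South Dakota,existing,351,147
Saskatchewan,existing,115,100
Wyoming,existing,571,1
Alberta,proposed,1413,632
Montana,proposed,998,260
Nebraska,proposed,1208,500
North Dakota,proposed,1085,233
South Dakota,proposed,892,442
Saskatchewan,proposed,189,16
Wyoming,proposed,1316,41
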