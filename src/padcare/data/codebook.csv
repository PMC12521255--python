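code,label,system_part
S_1,Wearable health management devices,smart_devices
S_2,Portable health monitoring devices,smart_devices
S_3,Self-service medical check-up devices,smart_devices
S_4,Home smart care monitoring devices,smart_devices
S_5,Home service robots,smart_devices
S_6,Catering service apps,online_software
S_7,Life service apps,online_software
S_8,Shopping service apps,online_software
S_9,Medical service apps,online_software
S_10,Travel service apps,online_software
S_11,Entertainment service apps,online_software
S_12,Meal assistance services,offline_services
S_13,Life care services,offline_services
S_14,Mobility assistance services,offline_services
S_15,Home medical care services,offline_services
S_16,Offline medical care services,offline_services
S_17,Mental comfort services,offline_services
S_18,Emergency assistance services,offline_services
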