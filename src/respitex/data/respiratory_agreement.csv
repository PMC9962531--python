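met,device_count,reference_count
4.8,15,13
6.8,20,21
9.6,30,27
13.5,40,40
16.1,56,55
19.8,58,59
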