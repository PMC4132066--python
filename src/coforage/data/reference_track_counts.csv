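category,count
total_tracks,84
no_association,26
commute_only,10
travel_only,6
diving_while_associated,39
synchronous_diving,32
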