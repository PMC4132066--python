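id_a,id_b,assoc_duration_min,n_sync_dives,dive_duration_median_s,dive_duration_min_s,dive_duration_max_s,depth_median_m,depth_min_m,depth_max_m,postdive_median_s,postdive_min_s,postdive_max_s,surface_distance_median_m,surface_distance_min_m,surface_distance_max_m
ID35,ID56,4,1,4,4,4,1.1,1.1,1.1,,,,290.1,290.1,290.1
ID48,ID49,4.7,4,18,4,44,2.8,1,13.7,50,8,152,329.1,329.1,329.1
ID29,ID41,4.9,5,14,,,2.9,1.6,8,72,4,108,48.3,10.2,355.8
ID28,ID49,12.2,3,8,,,4.3,3.3,9.6,4,,,495.3,495.3,495.3
ID5,ID6,12.5,6,36,28,48,10.6,7.9,14.4,16,,,63.0,14.2,184.7
ID1,ID2,18.5,2,28,,,4.5,1,7.9,20,,,375.2,375.2,375.2
ID11,ID15,21.3,4,28,20,52,6.2,1.2,15.6,38,20,116,317.2,317.2,317.2
ID24,ID82,27.9,5,24,4,44,5.4,1,8.1,20,4,148,112.6,72.3,338.1
ID14,ID16,32.7,4,28,,,9.2,3.4,12.1,26,4,48,344.7,287.3,402.2
ID13,ID19,34.5,4,40,8,56,12.9,2.1,18.5,28,24,128,79.4,53.7,105.1
ID63,ID65,83.7,20,28,12,48,8.0,1,12.4,24,12,116,218.9,44.5,480.9
ID66,ID69,91.2,9,8,4,48,3.6,1.2,17.8,44,4,160,141.1,34.9,264
ID15,ID17,121.1,3,42,24,60,16.9,8.6,22.1,34,16,68,203.2,194.6,471.5
ID19,ID20,135.7,8,38,4,48,11.6,1.2,15.2,32,8,128,49.3,20.8,132.7
ID29,ID40,178.8,11,10,4,56,2.3,1.1,4,62,4,160,97.1,11.2,371.7
ID37,ID57,199.5,3,10,,,2.8,1.6,8.6,46,4,76,94.9,24.7,159.9
ID50,ID52,248.9,57,32,4,96,8.2,1.1,16.8,20,4,168,201.8,7.4,462.9
ID6,ID8,276.2,70,40,4,64,11.1,1.1,26.5,20,4,80,39.4,2.6,405.3
ID12,ID14,357.3,30,44,20,64,12.1,1.1,21.7,20,8,80,34.1,1.8,199.8
ID40,ID41,479.5,68,12,4,48,2.4,1,24.9,30,4,176,119.1,5.9,429.8
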