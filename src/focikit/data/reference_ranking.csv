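rank,variant_id,n,k,ssr,aicc_printed,aicw_printed,within_cutoff
1,10,49,10,40.9,156.0,0.730,True
2,18,49,11,40.0,158.3,0.236,True
3,2,49,12,40.9,162.9,0.023,False
4,14,49,13,39.2,164.5,0.010,False
5,8,49,7,80.8,180.3,0.0,False
6,6,49,8,77.3,181.0,0.0,False
7,12,49,9,72.7,181.0,0.0,False
8,20,49,10,72.5,184.0,0.0,False
9,4,49,11,72.4,187.3,0.0,False
10,9,49,10,83.0,190.7,0.0,False
11,17,49,11,83.0,194.0,0.0,False
12,13,49,13,71.6,194.0,0.0,False
13,1,49,12,83.0,197.5,0.0,False
14,16,49,12,91.7,202.4,0.0,False
15,5,49,8,169.6,219.5,0.0,False
16,7,49,7,285.0,242.1,0.0,False
17,11,49,9,285.1,248.0,0.0,False
18,19,49,10,285.2,251.1,0.0,False
19,3,49,11,285.1,254.5,0.0,False
20,15,49,12,285.1,258.0,0.0,False
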