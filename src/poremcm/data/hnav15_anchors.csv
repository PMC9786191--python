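channel,repeat,segment,anchor_relpos,anchor_resnum
hNav1.5,1,k,1,232
hNav1.5,1,o,29,273
hNav1.5,1,p,50,372
hNav1.5,1,i,1,387
hNav1.5,2,k,1,822
hNav1.5,2,o,1,834
hNav1.5,2,p,50,898
hNav1.5,2,i,1,913
hNav1.5,3,k,1,1317
hNav1.5,3,o,1,1329
hNav1.5,3,p,50,1419
hNav1.5,3,i,1,1444
hNav1.5,4,k,1,1640
hNav1.5,4,o,1,1652
hNav1.5,4,p,50,1711
hNav1.5,4,i,1,1746
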