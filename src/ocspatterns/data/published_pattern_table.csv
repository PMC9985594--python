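label,kind,n,percent,mean_rx,sd_rx,median_rx,q1_rx,q3_rx
Once-only,leaf,198422,41.7,1.0,1.0,1.0,1.0,1.0
Sporadic,leaf,65632,13.8,2.4,0.9,2.0,2.0,3.0
Any infrequent,super,33854,7.1,3.1,1.4,3.0,2.0,4.0
Infrequent only,leaf,1445,0.3,2.2,0.6,2.0,2.0,2.0
Sporadic and infrequent,leaf,32409,6.8,3.1,1.4,3.0,2.0,4.0
Any moderately frequent,super,27933,5.9,3.7,2.0,3.0,2.0,4.0
Moderately frequent only,leaf,155,0.0,2.7,0.9,2.0,2.0,3.0
"Sporadic, infrequent and moderately frequent",leaf,8836,1.9,5.3,2.2,5.0,4.0,6.0
Sporadic and moderately frequent,leaf,17371,3.6,3.0,1.3,3.0,2.0,4.0
Infrequent and moderately frequent,leaf,1571,0.3,2.6,1.0,2.0,2.0,3.0
Any frequent,super,150326,31.5,8.7,13.3,5.0,3.0,9.0
"Sporadic, infrequent, moderately frequent and frequent",leaf,39842,8.4,16.2,15.6,12.0,8.0,19.0
"Sporadic, infrequent and frequent",leaf,29432,6.2,6.8,6.3,6.0,4.0,8.0
"Sporadic, moderately frequent and frequent",leaf,17455,3.7,8.4,14.3,6.0,4.0,8.0
Sporadic and frequent,leaf,56661,11.9,3.8,5.3,3.0,2.0,4.0
"Infrequent, moderately frequent and frequent",leaf,3083,0.6,12.1,20.0,7.0,4.0,12.0
Infrequent and frequent,leaf,2136,0.4,4.9,10.1,3.0,2.0,5.0
Moderately frequent and frequent,leaf,809,0.2,18.0,26.6,9.0,6.0,19.0
Frequent only,leaf,908,0.2,39.4,66.1,20.0,4.0,46.0
Total,total,476167,100.0,3.9,8.2,2.0,1.0,4.0
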