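trial_id,phase,n_patients,n_arms,experimental_arms,control_arm,primary_endpoint,response_criteria
KEYNOTE-604,III,453,2,Pembrolizumab + EP/EC,Placebo + EP/EC,PFS and OS,RECIST 1.1
IMpower133,III,403,2,Atezolizumab + EC,Placebo + EC,PFS and OS,RECIST 1.1
EA5161,II,145,2,Nivolumab + EP/EC,EP/EC,PFS,RECIST 1.1
CASPIAN,III,805,3,Durvalumab + EP/EC;Durvalumab + tremelimumab + EP/EC,EP/EC,OS,RECIST 1.1
Reck2012,II,130,3,phased-ipilimumab + paclitaxel + carboplatin;concurrent-ipilimumab + paclitaxel + carboplatin,Placebo + paclitaxel + carboplatin,irPFS,mWHO & irRC
Reck2016,III,954,2,Ipilimumab + EP/EC,Placebo + EP/EC,OS,mWHO
EORTC,II,119,2,Pembrolizumab + EP/EC,Placebo + EP/EC,PFS,NR
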