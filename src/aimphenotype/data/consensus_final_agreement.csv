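aim_id,name,total_mean_pct,total_sd_pct,internal_final_pct,external_final_pct
1,Invasive bacterial infection,91,9,88,100
2,Frequent Streptococcus pyogenes upper respiratory infection,87,8,88,80
3,Pneumonia,82,14,100,80
4,Recurrent/persistent otitis media,87,19,100,100
5,Recurrent/persistent infectious sinusitis,80,17,88,100
6,Bordetella pertussis,98,6,100,100
7,Breakthrough varicella infection,94,9,88,100
8,Zoster (shingles),86,17,100,80
9,Urinary tract infection,89,7,88,100
10,Skin fungal infection,85,10,100,80
11,Viral infection confirmed by lab,85,21,100,100
12,Celiac disease,83,24,100,100
13,Kawasaki disease,84,11,75,80
14,Appendicitis,98,6,88,100
15,Autoimmune thyroiditis,82,25,88,80
16,Diabetes type 1,90,17,88,100
17,Diabetes type 2,90,17,88,100
18,Inflammatory bowel disease,77,18,100,80
19,JRA/JIA/RA,84,16,100,100
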