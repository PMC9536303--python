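group	n_mirnas	n_pairs
Adenocarcinoma	551	51455
Adrenal Gland Neoplasms	431	22150
Biliary Tract Neoplasms	1050	147665
Brain Neoplasms	1679	267717
Breast Neoplasms	1762	288200
Colorectal Neoplasms	1821	304757
Endocrine Gland Neoplasm	39	241
Esophageal Neoplasms	1806	301059
Eye Neoplasms	125	2885
Head and Neck Neoplasms	1249	155197
Hematologic Neoplasms	54	492
Intestinal Neoplasms	403	28209
Kidney Neoplasms	1252	152880
Leukemia	286	15275
Liver Neoplasms	1463	266584
Lung Neoplasms	1736	282743
Lymphoma	1330	177172
Nerve Tissue Neoplasms	211	7005
Ovarian Neoplasms	1404	245655
Pancreatic Neoplasms	1701	272487
Pleural Neoplasms	112	2928
Prostatic Neoplasms	1110	164209
Sarcoma	1378	235334
Skin Neoplasms	1197	143565
Squamous Cell Carcinomas	884	118173
Stomach Neoplasms	1660	260636
Testicular Neoplasms	178	4690
Thyroid Neoplasms	1108	126140
Urinary Bladder Neoplasms	1528	224985
Uterine Neoplasms	329	18475
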