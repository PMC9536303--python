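group	members
Brain neoplasms	hsa-miR-3689e;hsa-miR-4422;hsa-miR-4432;hsa-miR-4720-3p;hsa-miR-5002-3p;hsa-miR-548ao-5p;hsa-miR-5688;hsa-miR-6511b-5p;hsa-miR-6719-3p;hsa-miR-6753-3p;hsa-miR-6811-5p;hsa-miR-7107-3p;hsa-miR-8062;hsa-miR-8067;hsa-miR-8068
Breast neoplasms	hsa-miR-1296-3p;hsa-miR-4273;hsa-miR-4422;hsa-miR-4445-3p;hsa-miR-4694-3p;hsa-miR-4720-3p;hsa-miR-5002-3p;hsa-miR-5011-3p;hsa-miR-548ae-5p;hsa-miR-548al;hsa-miR-548ao-5p;hsa-miR-5699-5p;hsa-miR-6724-5p;hsa-miR-6748-5p;hsa-miR-6753-3p;hsa-miR-6773-5p;hsa-miR-7107-3p
Colorectal neoplasms	hsa-miR-4273;hsa-miR-4293;hsa-miR-4422;hsa-miR-4432;hsa-miR-4445-3p;hsa-miR-4694-3p;hsa-miR-4720-3p;hsa-miR-5002-3p;hsa-miR-5011-3p;hsa-miR-548aj-5p;hsa-miR-548al;hsa-miR-6511b-5p;hsa-miR-6724-5p;hsa-miR-6753-3p;hsa-miR-6770-5p;hsa-miR-6773-5p;hsa-miR-6811-5p;hsa-miR-7107-3p;hsa-miR-7154-5p;hsa-miR-8068
Esophageal neoplasms	hsa-miR-1296-3p;hsa-miR-3974;hsa-miR-4273;hsa-miR-4445-3p;hsa-miR-4720-3p;hsa-miR-5002-3p;hsa-miR-548aj-5p;hsa-miR-548al;hsa-miR-548ao-5p;hsa-miR-5688;hsa-miR-5699-5p;hsa-miR-6511b-5p;hsa-miR-6719-3p;hsa-miR-6724-5p;hsa-miR-6748-5p;hsa-miR-6770-5p;hsa-miR-6773-5p;hsa-miR-6811-5p;hsa-miR-6828-3p;hsa-miR-7154-5p;hsa-miR-7515;hsa-miR-8062;hsa-miR-8067
Head and neck neoplasms	hsa-miR-3974;hsa-miR-5011-3p;hsa-miR-5702;hsa-miR-6828-3p
Kidney neoplasms	hsa-miR-1296-3p;hsa-miR-3689e;hsa-miR-4422;hsa-miR-5699-5p
Liver neoplasms	hsa-miR-3689e;hsa-miR-6724-5p;hsa-miR-6773-5p;hsa-miR-7154-5p;hsa-miR-7159-5p;hsa-miR-8062;hsa-miR-8067;hsa-miR-8068
Lung neoplasms	hsa-miR-4445-3p;hsa-miR-548al;hsa-miR-5688;hsa-miR-5702;hsa-miR-6511b-5p;hsa-miR-6811-5p;hsa-miR-7515
Ovarian neoplasms	hsa-miR-4273;hsa-miR-526a-5p;hsa-miR-6770-5p;hsa-miR-7156-5p;hsa-miR-7515
Pancreatic neoplasms	hsa-miR-3974;hsa-miR-4273;hsa-miR-4293;hsa-miR-4694-3p;hsa-miR-522-5p;hsa-miR-523-5p;hsa-miR-5702;hsa-miR-6770-5p;hsa-miR-6828-3p;hsa-miR-7156-5p;hsa-miR-7159-5p;hsa-miR-7515
Prostatic neoplasms	hsa-miR-1296-3p;hsa-miR-522-5p;hsa-miR-5699-5p;hsa-miR-6748-5p
Sarcoma	hsa-miR-5688;hsa-miR-7515;hsa-miR-8067
Skin neoplasms	hsa-miR-3689c;hsa-miR-3689e;hsa-miR-522-5p;hsa-miR-548ae-5p;hsa-miR-548ao-5p;hsa-miR-5688;hsa-miR-6753-3p;hsa-miR-6828-3p;hsa-miR-7107-3p;hsa-miR-7154-5p;hsa-miR-8062;hsa-miR-8068
Squamous cell carcinomas	hsa-miR-4293;hsa-miR-4694-3p;hsa-miR-548aj-5p
Stomach neoplasms	hsa-miR-4720-3p;hsa-miR-5002-3p;hsa-miR-5699-5p;hsa-miR-5702;hsa-miR-6719-3p;hsa-miR-6828-3p
Thyroid neoplasms	hsa-miR-4293;hsa-miR-4422;hsa-miR-5011-3p;hsa-miR-6753-3p;hsa-miR-7107-3p
Urinary bladder neoplasms	hsa-miR-6719-3p;hsa-miR-6724-5p;hsa-miR-6773-5p;hsa-miR-8067
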