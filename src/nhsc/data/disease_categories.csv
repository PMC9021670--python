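icd3,category_id,category_label
E11,1,Diabetes mellitus type 2
E86,2,Volume depletion and other disorders of electrolyte and acid-base balance
E87,2,Volume depletion and other disorders of electrolyte and acid-base balance
K08,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
K21,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
K25,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
K26,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
K29,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
K52,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
K57,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
K59,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
K62,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
R13,3,"Gastrointestinal ulcers and inflammation, esophageal reflux disease, functional bowel disorders, dysphagia"
A04,4,Intestinal infections
A08,4,Intestinal infections
A09,4,Intestinal infections
R11,4,Intestinal infections
N18,5,"Chronic kidney disease, cystitis, other diseases of the urinary system"
N30,5,"Chronic kidney disease, cystitis, other diseases of the urinary system"
N39,5,"Chronic kidney disease, cystitis, other diseases of the urinary system"
F01,6,"Dementia (vascular or Alzheimer's disease, primary Parkinson's syndrome)"
G20,6,"Dementia (vascular or Alzheimer's disease, primary Parkinson's syndrome)"
G30,6,"Dementia (vascular or Alzheimer's disease, primary Parkinson's syndrome)"
F05,7,"Mental disorders, personality or behavioral disorders, depressive disorder, schizoaffective disorder and schizophrenia, delirium"
F06,7,"Mental disorders, personality or behavioral disorders, depressive disorder, schizoaffective disorder and schizophrenia, delirium"
F07,7,"Mental disorders, personality or behavioral disorders, depressive disorder, schizoaffective disorder and schizophrenia, delirium"
F10,7,"Mental disorders, personality or behavioral disorders, depressive disorder, schizoaffective disorder and schizophrenia, delirium"
F20,7,"Mental disorders, personality or behavioral disorders, depressive disorder, schizoaffective disorder and schizophrenia, delirium"
F32,7,"Mental disorders, personality or behavioral disorders, depressive disorder, schizoaffective disorder and schizophrenia, delirium"
F33,7,"Mental disorders, personality or behavioral disorders, depressive disorder, schizoaffective disorder and schizophrenia, delirium"
G35,8,"Other diseases of the nervous system (MS, epilepsy)"
G40,8,"Other diseases of the nervous system (MS, epilepsy)"
H25,9,Cataracta senilis
D50,10,Anemias of different origin
D64,10,Anemias of different origin
I10,11,"Hypertension, hypotension, atherosclerosis, heart failure, thrombosis, phlebitis and thrombophlebitis"
I50,11,"Hypertension, hypotension, atherosclerosis, heart failure, thrombosis, phlebitis and thrombophlebitis"
I70,11,"Hypertension, hypotension, atherosclerosis, heart failure, thrombosis, phlebitis and thrombophlebitis"
I80,11,"Hypertension, hypotension, atherosclerosis, heart failure, thrombosis, phlebitis and thrombophlebitis"
I95,11,"Hypertension, hypotension, atherosclerosis, heart failure, thrombosis, phlebitis and thrombophlebitis"
J10,12,"Other acute/chronic lower respiratory tract infections and influenza, sore throat and chest pain"
J20,12,"Other acute/chronic lower respiratory tract infections and influenza, sore throat and chest pain"
J22,12,"Other acute/chronic lower respiratory tract infections and influenza, sore throat and chest pain"
J40,12,"Other acute/chronic lower respiratory tract infections and influenza, sore throat and chest pain"
J44,12,"Other acute/chronic lower respiratory tract infections and influenza, sore throat and chest pain"
R07,12,"Other acute/chronic lower respiratory tract infections and influenza, sore throat and chest pain"
A46,13,"Skin infections, decubital ulcer and pressure zone, skin cancer exclusive melanoma"
C44,13,"Skin infections, decubital ulcer and pressure zone, skin cancer exclusive melanoma"
L02,13,"Skin infections, decubital ulcer and pressure zone, skin cancer exclusive melanoma"
L89,13,"Skin infections, decubital ulcer and pressure zone, skin cancer exclusive melanoma"
M54,14,"Back pain, disturbances of gait and mobility"
R26,14,"Back pain, disturbances of gait and mobility"
S00,15,Superficial injuries of various parts of the body
S01,15,Superficial injuries of various parts of the body
S20,15,Superficial injuries of various parts of the body
S30,15,Superficial injuries of various parts of the body
S70,15,Superficial injuries of various parts of the body
S80,15,Superficial injuries of various parts of the body
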