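# Default 40-category condensed cause-of-death list for mortality analysis
# at ages 60 and over.  Categories are mutually exclusive and jointly cover
# every ICD-10 chapter letter A-Z.  Common cancers are kept singular;
# dementias are pooled across chapters (F00-F03 with G30); external-cause
# mechanism codes are pooled with the nature-of-injury codes (S, T); the
# final category collects U and Z codes, which are not valid underlying
# causes but occur as contributing causes.  Best-effort reconstruction of a
# national condensed list; replace with a custom file for other settings.
pattern,category
A,"Infectious, parasitic disease"
B,"Infectious, parasitic disease"
C18-C21,Colorectal cancer
C22,Liver cancer
C25,Pancreatic cancer
C33-C34,"Lung, tracheal cancer"
C43-C44,"Melanoma, malignant skin cancer"
C50,Breast cancer
C61,Prostate cancer
C81-C96,"Lymph, blood cancer"
C00-C17,Other malignant neoplasm
C23-C24,Other malignant neoplasm
C26-C32,Other malignant neoplasm
C35-C42,Other malignant neoplasm
C45-C49,Other malignant neoplasm
C51-C60,Other malignant neoplasm
C62-C80,Other malignant neoplasm
C97-C99,Other malignant neoplasm
D,"Benign neoplasm, blood, metabolic disease"
E40-E99,"Benign neoplasm, blood, metabolic disease"
E10-E14,Diabetes
E00-E09,Other endocrine disease
E15-E39,Other endocrine disease
F00-F03,"Dementia, Alzheimer's disease"
G30,"Dementia, Alzheimer's disease"
F04-F99,Other mental disorder
G20-G21,Parkinson's disease
G00-G19,Other neurological condition
G22-G29,Other neurological condition
G31-G99,Other neurological condition
H,"Eye, ear disease"
I10-I15,Hypertensive disease
I20-I25,Ischaemic heart disease
I44-I49,Cardiac arrhythmia
I50-I51,Heart failure
I60-I69,Cerebrovascular disease
I00-I09,Other circulatory disease
I16-I19,Other circulatory disease
I26-I43,Other circulatory disease
I52-I59,Other circulatory disease
I70-I99,Other circulatory disease
J09-J18,"Influenza, pneumonia"
J40-J47,Chronic lower respiratory disease
J00-J08,Other respiratory disease
J19-J39,Other respiratory disease
J48-J99,Other respiratory disease
K70-K77,Liver disease
K00-K69,Other digestive disease
K78-K99,Other digestive disease
L,Skin disease
M,Musculoskeletal disease
N00-N29,Kidney disease
N30-N99,Other genitourinary disease
O,"Reproductive, maternal condition"
P,"Perinatal condition, congenital malformation"
Q,"Perinatal condition, congenital malformation"
R,"Symptoms, signs, ill-defined condition"
S,"External cause mechanisms, traumatic injuries"
T,"External cause mechanisms, traumatic injuries"
V,"External cause mechanisms, traumatic injuries"
W20-W99,"External cause mechanisms, traumatic injuries"
X00-X59,"External cause mechanisms, traumatic injuries"
X85-X99,"External cause mechanisms, traumatic injuries"
Y00-Y86,"External cause mechanisms, traumatic injuries"
Y87.1-Y87.9,"External cause mechanisms, traumatic injuries"
Y88-Y99,"External cause mechanisms, traumatic injuries"
W00-W19,Accidental falls
X60-X84,Intentional self-harm
Y87.0,Intentional self-harm
U,Other U and Z codes
Z,Other U and Z codes
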