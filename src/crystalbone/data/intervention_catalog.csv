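name,kind,pattern,pharmacologic
dual-energy x-ray absorptiometry (axial),proc,CPT:77080,no
dual-energy x-ray absorptiometry (appendicular),proc,CPT:77081,no
vertebral fracture assessment,proc,CPT:77086,no
quantitative computed tomography,proc,CPT:77078,no
radiographic absorptiometry,proc,CPT:77083,no
bone density ultrasound,proc,CPT:76977,no
single-photon absorptiometry,proc,CPT:78350,no
dual-photon absorptiometry,proc,CPT:78351,no
bone turnover markers (collagen crosslinks),proc,CPT:82523,no
bone turnover markers (osteocalcin),proc,CPT:83937,no
alendronate,med,alendronate,yes
ibandronate,med,ibandronate,yes
risedronate,med,risedronate,yes
zoledronic acid,med,zoledronic acid,yes
abaloparatide,med,abaloparatide,yes
denosumab,med,denosumab,yes
raloxifene,med,raloxifene,yes
bazedoxifene,med,bazedoxifene,yes
romosozumab,med,romosozumab,yes
teriparatide,med,teriparatide,yes
calcitonin,med,calcitonin,yes
osteoporosis (ICD-10 M80),dx,ICD10:M80,no
osteoporosis (ICD-10 M81),dx,ICD10:M81,no
osteoporosis (ICD-9 733.0),dx,ICD9:733.0,no
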