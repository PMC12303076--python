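name,category,drug_classes,maintenance_flag
7+3,Intensive chemotherapy,cytarabine;anthracycline,false
Midostaurin-7+3,Intensive chemotherapy,cytarabine;anthracycline;midostaurin,false
GO-7+3,Intensive chemotherapy,cytarabine;anthracycline;gemtuzumab_ozogamicin,false
Aza-Ven,Non-intensive therapy,azacitidine;venetoclax,false
Azacitidine,Non-intensive therapy,azacitidine,false
Gilteritinib,Targeted therapy,gilteritinib,false
Hydroxyurea,Palliative,hydroxycarbamide,false
Auto-SCT,HSCT,,false
Allo-SCT,HSCT,,false
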