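atc_code,drug_class,drug_name
L01FC01,daratumumab,daratumumab
L01FC02,isatuximab,isatuximab
L01FX08,elotuzumab,elotuzumab
L01XG01,bortezomib,bortezomib
L01XG02,carfilzomib,carfilzomib
L01XG03,ixazomib,ixazomib
L04AX04,lenalidomide,lenalidomide
L04AX06,pomalidomide,pomalidomide
L04AX02,thalidomide,thalidomide
L04AX91,iberdomide,iberdomide
L01AA03,melphalan,melphalan
L01AA01,cyclophosphamide,cyclophosphamide
H02AB02,corticosteroid,dexamethasone
H02AB07,corticosteroid,prednisone
H02AB06,corticosteroid,prednisolone
L01FX24,teclistamab,teclistamab
L01FX27,elranatamab,elranatamab
L01FX29,talquetamab,talquetamab
L01XL05,cart,ciltacabtagene autoleucel
L01XL07,cart,idecabtagene vicleucel
L01XX99,trial_drug,trial medication
L01BC01,cytarabine,cytarabine
L01DB02,anthracycline,daunorubicin
L01DB06,anthracycline,idarubicin
L01BC07,azacitidine,azacitidine
L01XX52,venetoclax,venetoclax
L01EX10,midostaurin,midostaurin
L01EX13,gilteritinib,gilteritinib
L01XX05,hydroxycarbamide,hydroxycarbamide
L01FX02,gemtuzumab_ozogamicin,gemtuzumab ozogamicin
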