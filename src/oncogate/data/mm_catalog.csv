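name,category,drug_classes,maintenance_flag
D-VRd,Anti-CD38,daratumumab;bortezomib;lenalidomide;corticosteroid,false
D-VTd,Anti-CD38,daratumumab;bortezomib;thalidomide;corticosteroid,false
D-VCd,Anti-CD38,daratumumab;bortezomib;cyclophosphamide;corticosteroid,false
D-VMP,Anti-CD38,daratumumab;bortezomib;melphalan;corticosteroid,false
D-Vd,Anti-CD38,daratumumab;bortezomib;corticosteroid,false
D-Rd,Anti-CD38,daratumumab;lenalidomide;corticosteroid,false
D-Pd,Anti-CD38,daratumumab;pomalidomide;corticosteroid,false
D-mono,Anti-CD38,daratumumab,false
Isa-KRd,Anti-CD38,isatuximab;carfilzomib;lenalidomide;corticosteroid,false
Isa-Kd,Anti-CD38,isatuximab;carfilzomib;corticosteroid,false
Isa-Pd,Anti-CD38,isatuximab;pomalidomide;corticosteroid,false
VRd,PI+IMID,bortezomib;lenalidomide;corticosteroid,false
VTd,PI+IMID,bortezomib;thalidomide;corticosteroid,false
VCd,PI+IMID,bortezomib;cyclophosphamide;corticosteroid,false
Pom-Vd,PI+IMID,pomalidomide;bortezomib;corticosteroid,false
IRd,PI+IMID,ixazomib;lenalidomide;corticosteroid,false
Vd,PI,bortezomib;corticosteroid,false
KRd,PI,carfilzomib;lenalidomide;corticosteroid,false
Kd,PI,carfilzomib;corticosteroid,false
PCd,IMID,pomalidomide;cyclophosphamide;corticosteroid,false
Rd,IMID,lenalidomide;corticosteroid,false
Pd,IMID,pomalidomide;corticosteroid,false
P-mono,IMID,pomalidomide,false
Lenalidomide maintenance,IMID,lenalidomide,true
Iberdomide maintenance,IMID,iberdomide,true
Tal-Pd,Bispecific,talquetamab;pomalidomide;daratumumab,false
Tec,Bispecific,teclistamab,false
Elr,Bispecific,elranatamab;corticosteroid,false
Trial,Bispecific,trial_drug,false
CAR-T,CAR-T,cart,false
EPd,Other,elotuzumab;pomalidomide;corticosteroid,false
ERd,Other,elotuzumab;lenalidomide;corticosteroid,false
Melphalan,Other,melphalan,false
Bridging,Other,cyclophosphamide,false
Auto-SCT,HSCT,,false
Allo-SCT,HSCT,,false
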