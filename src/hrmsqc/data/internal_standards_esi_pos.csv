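identifier,name,mz,rt,polarity,role,ms2_key
benzothiazole_d4,Benzothiazole-d4,124.0807,5.56,positive,internal_standard,
lidocaine_d10,Lidocaine-d10,245.2433,5.31,positive,internal_standard,
chloridazon_d5,Chloridazon-d5,227.0743,6.50,positive,internal_standard,
irbesartan_d4,Irbesartan-d4,433.2648,8.87,positive,internal_standard,
darunavir_d9,Darunavir-d9,557.2990,10.41,positive,internal_standard,
propazine_d6,Propazine-d6,236.1544,11.00,positive,internal_standard,
azoxystrobin_d4,Azoxystrobin-d4,408.1492,11.80,positive,internal_standard,
diazinon_d10,Diazinon-d10,315.1711,14.10,positive,internal_standard,
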