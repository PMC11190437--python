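protein_id,name,orthologue_family,recruitment_class,conservation,flagellum_bias,rnai_phenotype
FBF1,FBF1,FBF1,before_duplication,beyond_kinetoplastids,equal,assembly_defect
TFP104,TFP104,,before_duplication,kinetoplastid_only,old_enriched,length_defect
TFP101,TFP101,TFP101,before_duplication,beyond_kinetoplastids,equal,untested
TFP61,TFP61,,before_duplication,kinetoplastid_only,equal,untested
TFP39,TFP39,,before_duplication,kinetoplastid_only,old_enriched,none
TFP59,TFP59,,before_duplication,kinetoplastid_only,equal,untested
TFP49,TFP49,,before_duplication,kinetoplastid_only,equal,length_defect
TFP64,TFP64,,before_duplication,kinetoplastid_only,equal,untested
BBP96,BBP96,,before_duplication,kinetoplastid_only,equal,untested
BBP86,BBP86,,before_duplication,kinetoplastid_only,equal,untested
TFP123,TFP123,,before_duplication,kinetoplastid_only,equal,none
TFP131,TFP131,,before_duplication,kinetoplastid_only,equal,untested
TFP17,TFP17,,before_duplication,kinetoplastid_only,equal,none
TFP72,TFP72,,before_duplication,kinetoplastid_only,new_enriched,none
TFP82,TFP82,TFP82,before_duplication,beyond_kinetoplastids,equal,untested
CEP164A,CEP164A,CEP164,after_duplication,beyond_kinetoplastids,equal,untested
TFP68,TFP68,,after_duplication,kinetoplastid_only,equal,assembly_defect
TFP52,TFP52,,after_duplication,kinetoplastid_only,equal,none
CEP19,CEP19,CEP19,after_duplication,beyond_kinetoplastids,equal,assembly_defect
TFP32,TFP32,,after_duplication,kinetoplastid_only,equal,untested
TFP62,TFP62,,after_duplication,kinetoplastid_only,equal,none
ARL3C,ARL3C,,after_duplication,kinetoplastid_only,equal,untested
SPB1,SPB1,SPB1,after_duplication,beyond_kinetoplastids,equal,none
CEP164B,CEP164B,CEP164,after_duplication,beyond_kinetoplastids,equal,untested
RABL2B,RABL2B,RABL2B,after_duplication,beyond_kinetoplastids,old_enriched,assembly_defect
CUL4B,CUL4B,,after_duplication,kinetoplastid_only,equal,growth_defect_only
TFP122,TFP122,,after_duplication,kinetoplastid_only,old_enriched,length_defect
CEP164C,CEP164C,CEP164,after_duplication,beyond_kinetoplastids,equal,untested
OFD1,OFD1,OFD1,probasal,beyond_kinetoplastids,equal,assembly_defect
CEP90,CEP90,CEP90,probasal,beyond_kinetoplastids,equal,assembly_defect
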