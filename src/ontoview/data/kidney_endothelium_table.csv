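AS/4/LABEL,AS/4/ID,AS/5/LABEL,AS/5/ID,CT/1/LABEL,CT/1/ID
vasa recta descending limb,UBERON:0009202,endothelium,UBERON:0001986,vasa recta descending limb cell,CL:1001285
vasa recta ascending limb,UBERON:0009091,endothelium,UBERON:0001986,vasa recta ascending limb cell,CL:1001131
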