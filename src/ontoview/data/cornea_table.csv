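AS/1/LABEL,AS/1/ID,AS/2/LABEL,AS/2/ID,AS/3/LABEL,AS/3/ID,CT/1/LABEL,CT/1/ID
eye,UBERON:0000970,cornea,UBERON:0000964,anterior stroma of cornea,UBERON:8000053,keratocyte,CL:0002363
eye,UBERON:0000970,cornea,UBERON:0000964,anterior stroma of cornea,UBERON:8000053,telocyte,CL:4033055
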