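AS/1,AS/1/LABEL,AS/1/ID,AS/2,AS/2/LABEL,AS/2/ID
Brain,brain,UBERON:0000955,Forebrain,forebrain,UBERON:0001890
Telencephalon,telencephalon,UBERON:0001893,Cranial nerve,cranial nerve,UBERON:0001785
Brain,brain,UBERON:0000955,Hindbrain,hindbrain,UBERON:0002028
Hindbrain,hindbrain,UBERON:0002028,Isthmus,midbrain-hindbrain boundary,UBERON:0003052
Midbrain,midbrain,UBERON:0001891,Isthmus,midbrain-hindbrain boundary,UBERON:0003052
Midbrain,midbrain,UBERON:0001891,Posterior (Midbrain),pretectal region,UBERON:0001944
Midbrain,midbrain,UBERON:0001891,Cranial nerve,cranial nerve,UBERON:0001785
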