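AS/1,AS/1/ID,AS/2,AS/2/ID,AS/3,AS/3/ID,AS/4,AS/4/ID
Neural crest,UBERON:0002342,Pharyngeal arch,UBERON:0002539,Pharyngeal arch 1,UBERON:0003114,Mandible,UBERON:0001684
Neural crest,UBERON:0002342,Pharyngeal arch,UBERON:0002539,Pharyngeal arch 1,UBERON:0003114,Maxilla,UBERON:0002397
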