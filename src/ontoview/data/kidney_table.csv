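AS/1/LABEL,AS/1/ID,AS/2/LABEL,AS/2/ID,AS/3/LABEL,AS/3/ID
kidney,UBERON:0002113,cortex of kidney,UBERON:0001225,medullary ray,UBERON:0009883
kidney,UBERON:0002113,cortex of kidney,UBERON:0001225,juxtamedullary cortex,UBERON:0005271
kidney,UBERON:0002113,cortex of kidney,UBERON:0001225,medullary ray,UBERON:0009883
kidney,UBERON:0002113,nephron,UBERON:0001285,renal corpuscle,UBERON:0001229
kidney,UBERON:0002113,nephron,UBERON:0001285,nephron tubule,UBERON:0001231
kidney,UBERON:0002113,renal collecting system,UBERON:0004100,collecting duct of renal tubule,UBERON:0001232
kidney,UBERON:0002113,renal papilla,UBERON:0001228,tip of renal papilla,UBERON:0009095
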