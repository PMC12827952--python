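# Cornea reference fragment.  The keratocyte is recorded as part of the
# substantia propria of the cornea (which encompasses anterior and posterior
# stroma); the telocyte is a widespread cell type with no corneal partonomy.
# Identifiers for terms whose ids the source tables do not print (anterior
# stroma of cornea, telocyte) are table-side approximations; the logic is
# id-agnostic.
#prop BFO:0000050 transitive
#label BFO:0000050 part of
#prop BFO:0000051 declare
#label BFO:0000051 has part
#prop RO:0002131 declare
#label RO:0002131 overlaps
#prop RO:0002170 declare
#label RO:0002170 connected to
#prop RO:0002202 declare
#label RO:0002202 develops from
#label UBERON:0000970 eye
#label UBERON:0000964 cornea
#label UBERON:0001777 substantia propria of cornea
#label UBERON:8000053 anterior stroma of cornea
#label CL:0002363 keratocyte
#label CL:4033055 telocyte
CL:0002363	BFO:0000050	UBERON:0001777
UBERON:8000053	BFO:0000050	UBERON:0001777
UBERON:0001777	BFO:0000050	UBERON:0000964
UBERON:0000964	BFO:0000050	UBERON:0000970
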