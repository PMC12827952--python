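# Kidney reference fragment: the unique adjacent-pair partonomy of the
# published kidney table extract, the podocyte classification/partonomy
# chain, and the ureter/kidney overlap.  Deliberately minimal: only
# relationships the source atlas documentation states are encoded.
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
#label UBERON:0002113 kidney
#label UBERON:0001225 cortex of kidney
#label UBERON:0009883 medullary ray
#label UBERON:0005271 juxtamedullary cortex
#label UBERON:0001285 nephron
#label UBERON:0001229 renal corpuscle
#label UBERON:0001231 nephron tubule
#label UBERON:0004100 renal collecting system
#label UBERON:0001232 collecting duct of renal tubule
#label UBERON:0001228 renal papilla
#label UBERON:0009095 tip of renal papilla
#label UBERON:0009202 vasa recta descending limb
#label UBERON:0009091 vasa recta ascending limb
#label UBERON:0001986 endothelium
#label UBERON:0005751 glomerular visceral epithelium
#label UBERON:0004188 glomerular epithelium
#label UBERON:0000056 ureter
#label CL:1001285 vasa recta descending limb cell
#label CL:1001131 vasa recta ascending limb cell
#label CL:0000653 podocyte
#label CL:0000066 epithelial cell
#label CL:0000000 cell
UBERON:0001225	BFO:0000050	UBERON:0002113
UBERON:0009883	BFO:0000050	UBERON:0001225
UBERON:0005271	BFO:0000050	UBERON:0001225
UBERON:0001285	BFO:0000050	UBERON:0002113
UBERON:0001229	BFO:0000050	UBERON:0001285
UBERON:0001231	BFO:0000050	UBERON:0001285
UBERON:0004100	BFO:0000050	UBERON:0002113
UBERON:0001232	BFO:0000050	UBERON:0004100
UBERON:0001228	BFO:0000050	UBERON:0002113
UBERON:0009095	BFO:0000050	UBERON:0001228
CL:0000653	BFO:0000050	UBERON:0005751
UBERON:0005751	BFO:0000050	UBERON:0001229
UBERON:0005751	subClassOf	UBERON:0004188
CL:0000653	subClassOf	CL:0000066
CL:0000066	subClassOf	CL:0000000
UBERON:0000056	RO:0002131	UBERON:0002113
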