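# Developing-brain fragment.  The midbrain-hindbrain boundary (isthmus)
# straddles both regions, so the reference ontology relates it to midbrain
# and hindbrain by overlaps, not part_of; cranial nerves are peripheral
# structures with no direct relation to the midbrain here.
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
#label UBERON:0000955 brain
#label UBERON:0001890 forebrain
#label UBERON:0002028 hindbrain
#label UBERON:0001891 midbrain
#label UBERON:0003052 midbrain-hindbrain boundary
#label UBERON:0001785 cranial nerve
#label UBERON:0001893 telencephalon
#label UBERON:0001944 pretectal region
UBERON:0003052	RO:0002131	UBERON:0001891
UBERON:0003052	RO:0002131	UBERON:0002028
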