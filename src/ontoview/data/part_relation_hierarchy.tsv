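# The part-relations hierarchy: part_of and has_part are subproperties of
# overlaps, and bounding_layer_of is a subproperty of part_of, so a reasoner
# infers that the kidney capsule is part of (and overlaps) the kidney from
# its asserted bounding_layer_of relationship alone.
#prop RO:0002131 declare
#label RO:0002131 overlaps
#prop BFO:0000050 subPropertyOf RO:0002131
#prop BFO:0000050 transitive
#label BFO:0000050 part of
#prop BFO:0000051 subPropertyOf RO:0002131
#label BFO:0000051 has part
#prop RO:0002007 subPropertyOf BFO:0000050
#label RO:0002007 bounding layer of
#label UBERON:0002113 kidney
#label UBERON:0002015 kidney capsule
UBERON:0002015	RO:0002007	UBERON:0002113
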