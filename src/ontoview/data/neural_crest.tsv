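# Neural-crest fragment.  The pharyngeal arch has a developmental
# contribution from the neural crest (RO:0002254) — a relationship that is
# real but unsafe for grouping annotations by location, because the arches
# also contain cells that do not originate in the neural crest.
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
#prop RO:0002254 declare
#label RO:0002254 has developmental contribution from
#label UBERON:0002342 neural crest
#label UBERON:0002539 pharyngeal arch
#label UBERON:0003114 pharyngeal arch 1
#label UBERON:0001684 mandible
#label UBERON:0002397 maxilla
UBERON:0002539	RO:0002254	UBERON:0002342
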