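product_substring	tag
relaxase	relaxase
mobilization protein	mob
mob protein	mob
type iv secretion	t4ss
t4ss	t4ss
virb	vir
vird4	vir
trag	tra
trab	tra
conjugal transfer	tra
portal protein	portal
portal vertex	portal
terminase large subunit	terminase
terminase small subunit	terminase
terminase	terminase
major capsid	capsid
capsid protein	capsid
tail fiber	tail
tail tape measure	tail
baseplate	tail
virion structural	virion
muf	muf
head morphogenesis	muf
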