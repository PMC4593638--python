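# Cross-species volume fractions (%) of the five gray-matter components,
# with stated uncertainties where available, and gray-matter volumes (cm^3,
# both hemispheres). Fractions compiled from published stereological and
# reconstruction studies; several entries were derived from primary
# neuroanatomy (length densities, diameters, spine densities and sizes)
# rather than measured directly. Empty fraction_pct marks a component not
# reported for that species. note=unspecified_glia marks glia entries that
# do not separate astrocytes from other glia.
species,component,fraction_pct,sd_pct,volume_cm3,note
mouse,axons,34.0,,0.12,
mouse,dendrites,35.0,,0.12,
mouse,spines,14.0,,0.12,
mouse,glia,11.0,,0.12,unspecified_glia
mouse,capillaries,0.7,0.1,0.12,
rat,axons,47.0,5.0,0.42,
rat,dendrites,35.0,5.0,0.42,
rat,spines,9.0,,0.42,
rat,glia,8.0,4.0,0.42,unspecified_glia
rat,capillaries,1.4,,0.42,
rabbit,axons,47.0,5.5,4.0,
rabbit,dendrites,34.7,3.9,4.0,
rabbit,spines,5.7,0.8,4.0,
rabbit,glia,12.7,2.2,4.0,unspecified_glia
rabbit,capillaries,,,4.0,
cat,axons,27.8,5.7,14.0,
cat,dendrites,31.0,6.3,14.0,
cat,spines,,,14.0,
cat,glia,15.5,,14.0,
cat,capillaries,2.1,0.5,14.0,
macaque,axons,,,42.9,
macaque,dendrites,33.0,19.0,42.9,
macaque,spines,4.5,0.8,42.9,
macaque,glia,,,42.9,
macaque,capillaries,0.9,0.1,42.9,
human,axons,,,571.8,
human,dendrites,35.4,23.7,571.8,
human,spines,14.8,9.9,571.8,
human,glia,11.5,3.4,571.8,
human,capillaries,1.7,0.3,571.8,
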