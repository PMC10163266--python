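# Demonstration endpoint characterization factors (hierarchist perspective,
# emission compartment: air). Units: DALY/kg for the two human-toxicity
# categories, species.yr/kg for the three ecotoxicity categories.
# NON-AUTHORITATIVE: real endpoint factor tables are externally licensed
# artifacts; these values only have field-plausible magnitudes so that the
# characterization arithmetic can be demonstrated and tested.
element,category,factor
Cr(VI),human carcinogenic toxicity,4.0e-2
Cr(VI),human non-carcinogenic toxicity,2.0e-4
Cr(III),human non-carcinogenic toxicity,1.0e-5
Cr(III),terrestrial ecotoxicity,5.0e-8
As,human carcinogenic toxicity,1.5e-2
As,human non-carcinogenic toxicity,3.0e-2
As,freshwater ecotoxicity,2.0e-8
As,marine ecotoxicity,4.0e-8
As,terrestrial ecotoxicity,2.0e-6
Zn,human non-carcinogenic toxicity,3.0e-3
Zn,freshwater ecotoxicity,1.0e-8
Zn,marine ecotoxicity,4.0e-8
Zn,terrestrial ecotoxicity,5.0e-6
Cu,human non-carcinogenic toxicity,5.0e-4
Cu,freshwater ecotoxicity,3.0e-8
Cu,marine ecotoxicity,1.0e-7
Cu,terrestrial ecotoxicity,3.0e-5
Ni,human carcinogenic toxicity,5.0e-4
Ni,human non-carcinogenic toxicity,2.0e-3
Ni,freshwater ecotoxicity,5.0e-9
Ni,marine ecotoxicity,2.0e-8
Ni,terrestrial ecotoxicity,1.0e-5
Pb,human carcinogenic toxicity,2.0e-4
Pb,human non-carcinogenic toxicity,5.0e-3
Pb,freshwater ecotoxicity,1.0e-9
Pb,marine ecotoxicity,2.0e-9
Pb,terrestrial ecotoxicity,1.0e-6
Cd,human carcinogenic toxicity,3.0e-3
Cd,human non-carcinogenic toxicity,8.0e-3
Cd,freshwater ecotoxicity,1.0e-8
Cd,marine ecotoxicity,2.0e-8
Cd,terrestrial ecotoxicity,3.0e-6
Co,human carcinogenic toxicity,1.0e-3
Co,human non-carcinogenic toxicity,1.0e-3
Co,freshwater ecotoxicity,2.0e-9
Co,marine ecotoxicity,5.0e-9
Co,terrestrial ecotoxicity,2.0e-6
Mn,human non-carcinogenic toxicity,1.0e-4
Mn,terrestrial ecotoxicity,1.0e-7
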