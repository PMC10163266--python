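# Demonstration snapshot (pinned 2023-05) of inhalation screening toxicity values.
# rfc in mg/m3, iur in (ug/m3)^-1. NON-AUTHORITATIVE: screening-level tables are
# living resources; supply a current table for regulatory use. Chromium is carried
# as the two species; total Cr has deliberately no entry of its own.
element,rfc,iur,source
Cr(VI),1.0e-4,1.2e-2,IRIS-style particulate Cr(VI) values
Cr(III),5.0e-3,,demonstration value (insoluble particulate)
As,1.5e-5,4.3e-3,IRIS-style inorganic arsenic values
Co,6.0e-6,9.0e-3,PPRTV-style cobalt values
Ni,9.0e-5,2.4e-4,refinery-dust-style nickel values
Mn,5.0e-5,,IRIS-style manganese value
Zn,3.0e-1,,demonstration value (route-extrapolated)
Cu,4.0e-2,,demonstration value
Pb,3.5e-3,1.2e-5,demonstration lead values
Cd,1.0e-5,1.8e-3,IRIS-style cadmium values
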