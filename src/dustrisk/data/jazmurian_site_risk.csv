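# Published site-level hazard indices and total cancer risks for the 11
# Jazmurian-basin dust-storm sampling sites (adult and 2-6 y child receptors),
# as printed at 2-3 significant figures. Used as a consistency fixture for the
# replicate assessment mode.
site,city,hi_adult,hi_child,cr_adult,cr_child
D1,Jiroft,1.19,5.28,1.33e-4,1.60e-3
D2,Jiroft,1.36,6.05,1.22e-4,1.46e-3
D3,Jiroft,1.38,6.13,0.85e-4,1.02e-3
D4,Roodbar Jonoob,1.33,5.91,1.25e-4,1.49e-3
D5,Roodbar Jonoob,1.23,5.46,1.11e-4,1.32e-3
D6,Ghaleh Ganj,1.06,4.70,1.67e-4,2.00e-3
D7,Ghaleh Ganj,1.06,4.73,1.14e-4,1.36e-3
D8,Kahnooj,0.71,3.19,1.05e-4,1.26e-3
D9,Kahnooj,1.11,4.93,0.91e-4,1.09e-3
D10,Iranshahr,1.09,4.85,1.59e-4,1.90e-3
D11,Iranshahr,1.19,5.28,4.17e-4,4.99e-3
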