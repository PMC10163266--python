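# US EPA default inhalation exposure parameters: adult resident and child aged 2-6.
# Units: inhr m3/day; ef days/year; ed years; bw kg; at_nc and at_ca days.
receptor,inhr,ef,ed,bw,at_nc,at_ca
adult,15,350,26,80,9490,25550
child,12.5,350,6,15,2190,25550
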