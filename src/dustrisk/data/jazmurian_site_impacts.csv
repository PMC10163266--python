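# Published endpoint impact assessment for the 11 Jazmurian-basin dust sites,
# per 1 g of particles, as printed at 3 significant figures. DALY for the two
# human categories and the human-health total; species.yr for the three
# ecotoxicity categories and the ecological total. Used as an internal
# additivity fixture (display rounding makes the printed ecological total equal
# the terrestrial value because freshwater/marine are ~3 orders smaller).
site,human_carcinogenic_daly,human_noncarcinogenic_daly,freshwater_species_yr,marine_species_yr,terrestrial_species_yr,human_health_total_daly,ecological_total_species_yr
D1,7.08e-10,9.62e-10,1.41e-15,6.97e-15,1.43e-12,16.7e-10,1.43e-12
D2,6.59e-10,9.62e-10,1.41e-15,6.96e-15,1.43e-12,16.2e-10,1.43e-12
D3,4.53e-10,9.43e-10,1.57e-15,7.00e-15,1.38e-12,13.9e-10,1.38e-12
D4,6.63e-10,8.44e-10,1.86e-15,12.1e-15,2.73e-12,15.1e-10,2.73e-12
D5,5.79e-10,5.90e-10,1.38e-15,7.53e-15,1.60e-12,11.7e-10,1.60e-12
D6,8.42e-10,6.16e-10,1.63e-15,6.74e-15,1.27e-12,14.6e-10,1.27e-12
D7,5.88e-10,7.17e-10,1.46e-15,6.65e-15,1.29e-12,13.0e-10,1.29e-12
D8,3.96e-10,7.38e-10,2.65e-15,23.1e-15,5.62e-12,11.3e-10,5.62e-12
D9,4.69e-10,7.39e-10,1.78e-15,10.7e-15,2.37e-12,12.1e-10,2.37e-12
D10,7.72e-10,6.95e-10,1.19e-15,5.51e-15,1.11e-12,14.6e-10,1.11e-12
D11,19.0e-10,11.2e-10,1.38e-15,5.76e-15,1.08e-12,30.2e-10,1.08e-12
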