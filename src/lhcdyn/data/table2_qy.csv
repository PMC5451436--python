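# Chlorophyll Qy vertical excitation energies (eV) per lumen state.
# Oscillator strengths are not tabulated for these lines; equal unit
# strengths are assigned, so only peak positions are meaningful.
label,energy_ev,strength
single_chla,2.042,1.0
high_ph_vio_pair,1.515,1.0
high_ph_vio_pair,1.500,1.0
low_ph_vio_pair,1.606,1.0
low_ph_vio_pair,1.521,1.0
low_ph_vio_pair,1.452,1.0
low_ph_vio_pair,1.414,1.0
low_ph_zea_pair,1.424,1.0
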