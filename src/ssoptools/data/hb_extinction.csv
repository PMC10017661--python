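# Molar extinction coefficients of human haemoglobin, cm^-1 / (mol/L).
# Compiled after the published whole-blood haemoglobin tabulation of
# S. Prahl (Oregon Medical Laser Center compilation, 1999 revision).
# version: 1
wavelength_nm,eps_hbo2,eps_hb
650,368.0,3750.12
660,319.6,3226.56
665,310.0,3116.80
670,294.0,2795.12
680,277.6,2407.92
850,1058.0,691.32
860,1070.0,726.44
870,1086.0,761.84
880,1102.2,794.28
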