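# Channel kinetics for the reduced layer-5 pyramidal cell.
# Sigmoid steady-state + Gaussian-plus-baseline tau parameterisation.
# Values are defaults of this package's reduced model, chosen to reproduce
# qualitative L5PC behaviour (adapting regular spiking, Ih sag); conductance
# densities live in the cell geometry file, not here.
channel	gate	parameter	value
NaT	m	v_half	-42.0
NaT	m	slope_k	6.0
NaT	m	power	3
NaT	m	tau_base	0.05
NaT	m	tau_amp	0.1
NaT	m	tau_vpeak	-40.0
NaT	m	tau_sigma	30.0
NaT	h	v_half	-62.0
NaT	h	slope_k	-6.0
NaT	h	power	1
NaT	h	tau_base	0.5
NaT	h	tau_amp	7.0
NaT	h	tau_vpeak	-60.0
NaT	h	tau_sigma	20.0
NaT	-	reversal	50.0
NaP	m	v_half	-52.6
NaP	m	slope_k	4.6
NaP	m	power	3
NaP	m	tau_base	0.8
NaP	m	tau_amp	1.5
NaP	m	tau_vpeak	-50.0
NaP	m	tau_sigma	30.0
NaP	h	v_half	-48.8
NaP	h	slope_k	-10.0
NaP	h	power	1
NaP	h	tau_base	1000.0
NaP	h	tau_amp	2000.0
NaP	h	tau_vpeak	-50.0
NaP	h	tau_sigma	40.0
NaP	-	reversal	50.0
K_transient	m	v_half	-47.0
K_transient	m	slope_k	11.0
K_transient	m	power	4
K_transient	m	tau_base	0.5
K_transient	m	tau_amp	1.5
K_transient	m	tau_vpeak	-70.0
K_transient	m	tau_sigma	30.0
K_transient	h	v_half	-66.0
K_transient	h	slope_k	-10.0
K_transient	h	power	1
K_transient	h	tau_base	8.0
K_transient	h	tau_amp	20.0
K_transient	h	tau_vpeak	-60.0
K_transient	h	tau_sigma	25.0
K_transient	-	reversal	-85.0
K_persistent	m	v_half	-11.0
K_persistent	m	slope_k	12.0
K_persistent	m	power	2
K_persistent	m	tau_base	1.5
K_persistent	m	tau_amp	6.0
K_persistent	m	tau_vpeak	-50.0
K_persistent	m	tau_sigma	25.0
K_persistent	h	v_half	-64.0
K_persistent	h	slope_k	-11.0
K_persistent	h	power	1
K_persistent	h	tau_base	360.0
K_persistent	h	tau_amp	500.0
K_persistent	h	tau_vpeak	-50.0
K_persistent	h	tau_sigma	30.0
K_persistent	-	reversal	-85.0
Kv3	m	v_half	-8.0
Kv3	m	slope_k	9.7
Kv3	m	power	1
Kv3	m	tau_base	0.5
Kv3	m	tau_amp	3.5
Kv3	m	tau_vpeak	-50.0
Kv3	m	tau_sigma	40.0
Kv3	-	reversal	-85.0
SK	-	reversal	-85.0
SK	-	ca_half	4.3e-4
SK	-	ca_hill	4.0
M	m	v_half	-35.0
M	m	slope_k	10.0
M	m	power	1
M	m	tau_base	30.0
M	m	tau_amp	60.0
M	m	tau_vpeak	-45.0
M	m	tau_sigma	30.0
M	-	reversal	-85.0
Ih	m	v_half	-91.0
Ih	m	slope_k	-8.0
Ih	m	power	1
Ih	m	tau_base	35.0
Ih	m	tau_amp	25.0
Ih	m	tau_vpeak	-85.0
Ih	m	tau_sigma	20.0
Ih	-	reversal	-45.0
CaHVA	m	v_half	-20.0
CaHVA	m	slope_k	6.0
CaHVA	m	power	2
CaHVA	m	tau_base	1.0
CaHVA	m	tau_amp	1.0
CaHVA	m	tau_vpeak	-30.0
CaHVA	m	tau_sigma	30.0
CaHVA	h	v_half	-45.0
CaHVA	h	slope_k	-12.0
CaHVA	h	power	1
CaHVA	h	tau_base	80.0
CaHVA	h	tau_amp	120.0
CaHVA	h	tau_vpeak	-50.0
CaHVA	h	tau_sigma	30.0
CaHVA	-	reversal	ca
CaLVA	m	v_half	-40.0
CaLVA	m	slope_k	6.0
CaLVA	m	power	2
CaLVA	m	tau_base	3.0
CaLVA	m	tau_amp	8.0
CaLVA	m	tau_vpeak	-70.0
CaLVA	m	tau_sigma	20.0
CaLVA	h	v_half	-90.0
CaLVA	h	slope_k	-6.4
CaLVA	h	power	1
CaLVA	h	tau_base	85.0
CaLVA	h	tau_amp	50.0
CaLVA	h	tau_vpeak	-80.0
CaLVA	h	tau_sigma	25.0
CaLVA	-	reversal	ca
leak	-	reversal	-80.0
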