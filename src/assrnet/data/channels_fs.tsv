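# Channel kinetics for the fast-spiking PV+ basket cell (single compartment).
# Fast Na+ inactivation recovery and a Kv3-like delayed rectifier give the
# high-frequency, weakly adapting firing typical of PV+ cells.
channel	gate	parameter	value
NaT	m	v_half	-38.0
NaT	m	slope_k	7.0
NaT	m	power	3
NaT	m	tau_base	0.04
NaT	m	tau_amp	0.06
NaT	m	tau_vpeak	-40.0
NaT	m	tau_sigma	30.0
NaT	h	v_half	-58.3
NaT	h	slope_k	-6.7
NaT	h	power	1
NaT	h	tau_base	0.25
NaT	h	tau_amp	3.0
NaT	h	tau_vpeak	-60.0
NaT	h	tau_sigma	20.0
NaT	-	reversal	50.0
Kv3	m	v_half	-12.4
Kv3	m	slope_k	6.8
Kv3	m	power	2
Kv3	m	tau_base	0.2
Kv3	m	tau_amp	2.0
Kv3	m	tau_vpeak	-50.0
Kv3	m	tau_sigma	30.0
Kv3	-	reversal	-85.0
leak	-	reversal	-70.0
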