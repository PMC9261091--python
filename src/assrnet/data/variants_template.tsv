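# Blank schema template for transcribing literature variant tables.
# One row per parameter delta; rows sharing an id form one variant and must
# agree on gene and channel.
#   id          free label, unique per variant (e.g. Ca7, HCN1-2)
#   gene        one of CACNA1C, CACNA1D, CACNB2, CACNA1I, SCN1A, HCN1, HCN1A
#   channel     one of CaHVA, CaLVA, Ih, NaT, NaP
#   gate        gate label (m, h); '-' for channel-level g_factor rows
#   param_class dv_shift (mV, additive) | slope_factor | tau_factor | g_factor
#   value       full literature effect; factors must be > 0
#   provenance  free text (citation)
id	gene	channel	gate	param_class	value	provenance
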