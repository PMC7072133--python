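sample_id	elisa	strip	lc_ms
CSF5	1	1	1
CSF6	1	1	1
CSF7	10	1	10
CSF8	1	1	1
CSF9	10	1	1
CSF10	10	10	10
CSF11	20	20	20
CSF12	20	20	20
CSF13	20	10	10
CSF14	10	10	10
CSF15	20	40	40
CSF16	20	20	20
CSF17	20	20	20
CSF18	30	40	40
CSF19	20	40	30
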