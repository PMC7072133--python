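sample_id	blood_fraction	strip_grade
CSF1	0.01	++++
CSF1	0.001	++++
CSF1	0.0001	+++
CSF1	0.00001	++
CSF1	0	negative
CSF2	0.01	++++
CSF2	0.001	++++
CSF2	0.0001	++++
CSF2	0.00001	+++
CSF2	0	++
CSF3	0.01	++++
CSF3	0.001	++++
CSF3	0.0001	+++
CSF3	0.00001	++
CSF3	0	negative
CSF4	0.01	++++
CSF4	0.001	++++
CSF4	0.0001	+++
CSF4	0.00001	++
CSF4	0	negative
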