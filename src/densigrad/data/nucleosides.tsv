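name	formula	neutral_mass
dC	C9H13N3O4	227.090606
5me-dC	C10H15N3O4	241.106256
5hm-dC	C10H15N3O5	257.101171
5f-dC	C10H13N3O5	255.085521
5ca-dC	C10H13N3O6	271.080435
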