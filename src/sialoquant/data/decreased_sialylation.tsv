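accession	protein_name	sequence	site	fold_change	p_value
O14672	Disintegrin and metalloproteinase domain-containing protein 10	NdeISQVLEK	N439	0.57	0.0149
P07602	Proactivator polypeptide	NdeSTKQEILAALEK	N426	0.57	0.0474
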