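# Residue-name alias table: name <TAB> base_type <TAB> variant
# Editable; ships as data so PDB-entry-specific component codes can be
# added without touching code.  Codes for 2'-modified guanosines vary by
# deposition -- validate against the chemical component dictionary of the
# entry being analyzed before relying on the variant label.
DG	G	deoxy
DA	A	deoxy
DC	C	deoxy
DT	T	deoxy
DU	U	deoxy
G	G	ribo
A	A	ribo
C	C	ribo
U	U	ribo
GF2	G	2F-ribo
AF2	A	2F-ribo
CF2	C	2F-ribo
UF2	U	2F-ribo
LCG	G	LNA
LCA	A	LNA
LCC	C	LNA
GFL	G	2F-arabino
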