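gene	allele	category	notes
RET	G810C	solvent_front	bulky substitution at the solvent-exposed pocket edge; steric clash with selective RET inhibitors
RET	G810S	solvent_front	solvent front substitution
RET	G810R	solvent_front	solvent front substitution
RET	V804M	gatekeeper	ATP-pocket gatekeeper substitution
RET	V804L	gatekeeper	ATP-pocket gatekeeper substitution
RET	Y806C	roof	pocket-roof residue adjacent to the gatekeeper; resistance in cis with V804
RET	T1078M	vus	variant of uncertain significance, presumed passenger
RET	M918T	oncogenic_activating	canonical MTC activating mutation
RET	G601E	oncogenic_activating	activating mutation seen after multikinase therapy
RET	K666E	oncogenic_activating	activating mutation seen after multikinase therapy
RET	D898Y	oncogenic_activating	activating mutation seen after multikinase therapy
KRAS	G12*	oncogenic_activating	codon 12 activating substitutions
KRAS	G13*	oncogenic_activating	codon 13 activating substitutions
KRAS	Q61*	oncogenic_activating	codon 61 activating substitutions
KRAS	A59*	oncogenic_activating	codon 59 activating alterations incl. in-frame deletion
NRAS	G12*	oncogenic_activating	codon 12 activating substitutions
NRAS	G13*	oncogenic_activating	codon 13 activating substitutions
NRAS	Q61*	oncogenic_activating	codon 61 activating substitutions
NRAS	A59*	oncogenic_activating	codon 59 activating alterations
BRAF	V600*	oncogenic_activating	class I activating substitutions
BRAF	D594*	oncogenic_activating	kinase-impaired class III alleles, RAS-dependent
MET	*	amplification_target	bypass via receptor amplification
FGFR1	*	amplification_target	bypass via receptor amplification
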