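# Probe-remnant and search modification registry. delta_mass is the monoisotopic mass
# shift in Da; targets is the set of residue letters the modification may occupy;
# formula (when known) allows the delta to be validated from atomic masses.
name	delta_mass	targets	kind	formula
vps_dadps	387.1940	C	variable
vps_dde	344.1631	C	variable
vs	192.0569	C	variable
vme	172.0848	C	variable
pa	112.0637	C	variable
vpe_hydrolyzed	158.0691	C	variable
carbamidomethyl	57.0215	C	fixed	C2H3NO
oxidation	15.9949	M	variable	O
gg	114.0429	K	variable	C4H6N2O2
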