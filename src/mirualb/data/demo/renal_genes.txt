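# synthetic stand-in for a curated renal gene list
GENE000
GENE003
GENE006
GENE009
GENE012
GENE015
GENE018
GENE021
GENE024
GENE027
GENE030
GENE033
GENE036
GENE039
GENE042
GENE045
GENE048
GENE051
GENE054
GENE057
GENE060
GENE063
GENE066
GENE069
GENE072
GENE075
GENE078
GENE081
GENE084
GENE087
GENE090
GENE093
GENE096
GENE099
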