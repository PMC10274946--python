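# Prodigal-style 28-bin RBS table: bin 0 is the no-motif
# default; bins 1-27 rank motif strength first, spacer second.
motif	spacer	bin
GGA	11-15	1
GGA	3-4	2
GGA	5-10	3
GAG	11-15	4
GAG	3-4	5
GAG	5-10	6
AGG	11-15	7
AGG	3-4	8
AGG	5-10	9
AGGA	11-15	10
AGGA	3-4	11
AGGA	5-10	12
GGAG	11-15	13
GGAG	3-4	14
GGAG	5-10	15
GAGG	11-15	16
GAGG	3-4	17
GAGG	5-10	18
AGGAG	11-15	19
AGGAG	3-4	20
AGGAG	5-10	21
GGAGG	11-15	22
GGAGG	3-4	23
GGAGG	5-10	24
AGGAGG	11-15	25
AGGAGG	3-4	26
AGGAGG	5-10	27
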