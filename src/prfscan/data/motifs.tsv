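# Slippery-sequence motif catalog.
# name: run-length naming (e.g. threetwotwo = 3 identical bases, then 2,
#   then 2, read 5'->3', anchored so the 3' end abuts the empty A-site).
# id: fixed integer coding used as the MOTIF feature fed to the classifier.
# direction: -1 backward shift, +1 forward shift.
# runs: comma-separated run lengths, 5'->3'.
# precedence: 1 = matched first; longer patterns, then fewer runs, are
#   rarer by chance and take precedence over their sub-patterns.
name	id	direction	runs	precedence
six	0	-1	6	5
threethree	1	-1	3,3	6
fivetwo	2	-1	5,2	1
twofive	3	-1	2,5	2
twofour	4	-1	2,4	7
threetwotwo	5	-1	3,2,2	3
five	6	-1	5	8
twoonefour	7	-1	2,1,4	4
four	8	1	4	9
three	9	1	3	10
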