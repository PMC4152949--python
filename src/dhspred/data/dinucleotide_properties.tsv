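# Six B-DNA base-pair step (dinucleotide) structural parameters:
# angular twist/tilt/roll in degrees, translational shift/slide/rise in Angstrom.
# Values are consensus averages from crystallographic surveys of B-DNA steps
# (Olson et al., PNAS 95:11163, style of compilation), made exactly
# strand-symmetric: a step and its reverse complement share twist/roll/slide/rise
# while tilt and shift change sign.  The encoder z-scores each property across
# the 16 dinucleotides before use, so only relative differences matter.
# Replace via PropertyTable.from_tsv / the --properties CLI flag.
dinucleotide	twist	tilt	roll	shift	slide	rise
AA	35.10	-1.40	0.70	-0.03	-0.08	3.27
AC	31.50	-0.50	0.70	0.13	-0.58	3.36
AG	31.90	-1.70	4.50	0.09	-0.25	3.34
AT	29.30	0.00	1.10	0.00	-0.59	3.31
CA	37.30	-0.10	4.70	0.09	0.53	3.33
CC	32.90	-0.10	3.60	0.05	-0.22	3.42
CG	36.10	0.00	5.40	0.00	0.41	3.39
CT	31.90	1.70	4.50	-0.09	-0.25	3.34
GA	36.30	-1.50	1.90	-0.28	0.09	3.37
GC	33.60	0.00	0.30	0.00	-0.38	3.40
GG	32.90	0.10	3.60	-0.05	-0.22	3.42
GT	31.50	0.50	0.70	-0.13	-0.58	3.36
TA	37.80	0.00	3.30	0.00	0.05	3.42
TC	36.30	1.50	1.90	0.28	0.09	3.37
TG	37.30	0.10	4.70	-0.09	0.53	3.33
TT	35.10	1.40	0.70	0.03	-0.08	3.27
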