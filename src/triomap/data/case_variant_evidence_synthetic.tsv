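# SYNTHETIC reconstruction of the per-variant evidence inputs for the 11
# private homozygous protein-changing variants. The in-silico deleteriousness
# vote counts (0-5 tools) and impact classes are encoded from the narrative
# variant descriptions; the original supplementary evidence tables are not
# shipped. Frameshift/indel variants are not scorable by the missense
# predictors and carry 0 votes. All 11 variants segregate as case hom-alt
# with both parents heterozygous.
variant_id	gene	case	impact	votes	segregation_consistent
29:6343738:G:A	TYR	case1	MODERATE	5	1
PTBP2:case1	PTBP2	case1	MODERATE	3	1
LOC787891:case1	LOC787891	case1	MODERATE	0	1
ZNF226:case1	ZNF226	case1	MODERATE	3	1
FASN:case1	FASN	case1	MODERATE	1	1
MAGI1:case1	MAGI1	case1	MODERATE	3	1
28:40526902:G:T	GRID1	case2	MODERATE	4	1
GRIN2A:case2	GRIN2A	case2	MODERATE	3	1
OTOGL:case2	OTOGL	case2	MODERATE	1	1
RAD54B:case3	RAD54B	case3	HIGH	0	1
NSMF:case3	NSMF	case3	MODERATE	0	1
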