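# Cohort genotype counts for the 11 private homozygous protein-changing variants
# found in the three white-coat Simmental cases. Populations: <breed>_<cohort>,
# cohorts: wgs = whole-genome resequencing control cohort, array = routine
# SNP-array genotyping of Swiss dairy cattle. includes_case=1 marks the cell
# containing the affected (var/var) case animal.
variant_id	population	n_varvar	n_refvar	n_refref	includes_case
29:6343738:G:A	Simmental_wgs	1	2	237	1
29:6343738:G:A	others_wgs	0	0	5433	0
29:6343738:G:A	Simmental_array	0	0	1243	0
29:6343738:G:A	others_array	0	0	16534	0
PTBP2:case1	Simmental_wgs	1	4	235	1
PTBP2:case1	others_wgs	0	4	5429	0
LOC787891:case1	Simmental_wgs	1	21	218	1
LOC787891:case1	others_wgs	0	4	5429	0
ZNF226:case1	Simmental_wgs	1	15	226	1
ZNF226:case1	others_wgs	0	4	5429	0
ZNF226:case1	Simmental_array	1	77	1333	0
ZNF226:case1	others_array	0	30	17082	0
FASN:case1	Simmental_wgs	1	11	228	1
FASN:case1	others_wgs	0	1	5432	0
FASN:case1	Simmental_array	2	904	9645	0
FASN:case1	others_array	2	2311	37487	0
MAGI1:case1	Simmental_wgs	1	10	229	1
MAGI1:case1	others_wgs	0	0	5433	0
MAGI1:case1	Simmental_array	0	93	1274	0
MAGI1:case1	others_array	0	9	17097	0
28:40526902:G:T	Simmental_wgs	1	8	231	1
28:40526902:G:T	others_wgs	0	0	5433	0
28:40526902:G:T	Simmental_array	0	22	594	0
28:40526902:G:T	others_array	0	0	1744	0
GRIN2A:case2	Simmental_wgs	1	7	232	1
GRIN2A:case2	others_wgs	0	9	5424	0
GRIN2A:case2	Simmental_array	0	737	9791	0
GRIN2A:case2	others_array	0	721	37655	0
OTOGL:case2	Simmental_wgs	1	19	220	1
OTOGL:case2	others_wgs	0	3	5430	0
OTOGL:case2	Simmental_array	7	237	1144	0
OTOGL:case2	others_array	0	43	16884	0
RAD54B:case3	Simmental_wgs	1	11	228	1
RAD54B:case3	others_wgs	1	3	5429	0
NSMF:case3	Simmental_wgs	1	5	234	1
NSMF:case3	others_wgs	0	1	5432	0
NSMF:case3	Simmental_array	3	95	1311	0
NSMF:case3	others_array	0	65	17030	0
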