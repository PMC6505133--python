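# Published assembly statistics for the three European grayling assembly
# stages: 1 = short-read draft, 2 = long-read hybrid, 3 = chromosome-level
# (synteny + linkage). Absolute values only; percent changes between stages
# are recomputed, not stored.
statistic	stage1	stage2	stage3
n50	283328	390289	33018251
l50	1359	1030	20
n90	38415	49679	23618429
l90	6620	5397	40
scaffolds	24369	18265	51
total_length	1468519221	1575987192	1485210005
mean_length	60261	86285	29121765
min_length	975	984	6483087
max_length	2502076	4048953	44988017
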