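# name	gene	class	context	residues
g-head	MYH7	priming-g	blocked	1-16,18-21,449,453
f2-head	MYH7	priming-f2	blocked	22-61,524-525,533,536,652,657,663
g-tail	MYH7	priming-g	tail	62-76,858,870
f1-tail	MYH7	priming-f1	tail	894,898,901,903
f2-tail	MYH7	priming-f2	tail	77-96,894,898,901,903-904,906,908
h-blocked	MYH7	anchoring-h	blocked	17,97-101
i-blocked	MYH7	anchoring-i	blocked	102-111,716,719,723
j-blocked	MYH7	anchoring-j	blocked	112-114,116-142,145,147-168,171-177,179-180,182-192,194-198,200,202-203,205-213,215-231,233-238,240-242,250-255,257-258,483,493,497,515,731,733,736,739-741,749,758,762
d1-blocked	MYH7	stabilizing-d1	blocked	169-170,259-262,264-266,268-282,284-290,292-306,308,310-313,403,442
d1-free	MYH7	stabilizing-d1	free	314-317,406,410-411,449,453
d2-free	MYH7	stabilizing-d2	free	172-177,179-180,182-192,194-198,200,202-203,205-213,215-231,233-238,240-242,250-255,257-258,318-321,369,374,381,483,493,497,515,716,719,723,733,736,739-741,762-763,766
e-blocked	MYH7	stabilizing-e	blocked	322,324-327,329-331,386,606
a-tail	MYH7	stabilizing-a	tail	332-337,339-350,352-353,915,924,928-930
scELC-conv-blocked	MYH7	scaffolding-ELC	blocked	172-177,179-180,182-192,194-198,200,202-203,205-210,355-358,716,719,723,731,733,736,739-741,749,758,762
scELC-conv-free	MYH7	scaffolding-ELC	free	763
scELC-neck-blocked	MYH7	scaffolding-ELC	blocked	359-368,370-373,375-380,382-385,387-402,404-405,407-409,781,783,787,797,811
scELC-neck-free	MYH7	scaffolding-ELC	free	359-368,370-373,375-380,382-385,387-402,404-405,407-409,781,783,787,797,811
scRLC-blocked	MYH7	scaffolding-RLC	blocked	412-426,428-430,811,834,842
scRLC-free	MYH7	scaffolding-RLC	free	412-426,428-430,811,834,842
md-nucleotide	MYH7	MD-nucleotide	either	178,181,239,243-245,431-441,443-448,450-452,454-456,458-466,469
md-actin	MYH7	MD-actin	either	204,214,374,381,403,406,410-411,467-468,470-477,480-482,484-492,494-496,498-514,516-520,533,536,567,576,606
md-converter	MYH7	MD-converter	either	522-523,526-532,534-535,537-566,568-575,577-583,710,716,719,723,733,736,739,741,762-763,766,768
md-relay	MYH7	MD-relay	either	493,497,515,585,587-596,598-605,607-611
md210-extra	MYH7	other	either	612-627
mesa	MYH7	mesa	either	1-100,143-144,146,169-170,193,199,201,204,214,249,256,338,403,406,442,449,453,497,515,525,536,584,606,628-670,673-689,691-701,703-722,724-740,742-748,750-762,764-782,784-786,788-790
lmm	MYH7	LMM	either	1161-1935
elc-anchoring-i	MYL3	anchoring-i	blocked	149,155
elc-stab-e	MYL3	stabilizing-e	free	149,155
elc-scaff-blocked	MYL3	scaffolding-ELC	blocked	149,155
elc-scaff-free	MYL3	scaffolding-ELC	free	155
rlc-regulating	MYL2	regulating-RLC-RLC	either	22,58
rlc-scaff	MYL2	scaffolding-RLC	either	22,58
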