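#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
tgt7                 -            101 toyfam               -             33   2.2e-57  179.7  11.0   1   2   2.7e-30   3.8e-30   92.6   1.9     1    33    11    43    11    43 1.00 -
tgt7                 -            101 toyfam               -             33   2.2e-57  179.7  11.0   2   2   2.7e-30   3.8e-30   92.6   1.9     1    33    59    91    59    91 1.00 -
tgt1                 -             78 toyfam               -             33   1.7e-30   93.7   1.9   1   1   1.5e-30   2.2e-30   93.3   1.9     1    33    21    53    21    53 1.00 -
tgt2                 -             81 toyfam               -             33   1.8e-30   93.6   1.9   1   1   1.7e-30   2.4e-30   93.2   1.9     1    33    24    56    24    56 1.00 -
tgt3                 -             84 toyfam               -             33   1.9e-30   93.5   1.9   1   1   1.8e-30   2.6e-30   93.1   1.9     1    33    27    59    27    59 1.00 -
tgt4                 -             87 toyfam               -             33   2.1e-30   93.4   1.9   1   1     2e-30   2.8e-30   93.0   1.9     1    33    30    62    30    62 1.00 -
#
# Program:         hmmsearch
# Version:         3.4 (Aug 2023)
# Pipeline mode:   SEARCH
# Query file:      toy.hmm
# Target file:     targets.fa
# Option settings: hmmsearch --domtblout /root/pkg/tests/data/toyfam.domtbl -E 1000 --domE 1000 toy.hmm targets.fa 
# Current dir:     /root/pkg/scratch
# Date:            Wed Sep 30 23:41:51 2026
# [ok]
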