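# Published ordered decision list for MACROD2 deletion status from SNP-array
# LRR signals: 8 homozygous-deletion rules, 8 wild-type rules, and a default
# heterozygous-deletion rule. Support/accuracy are the reported percentages.
IF rs353149 <= -0.3811 AND rs6034087 <= -0.2724 THEN class = Homozygous deletion [support=5.84 accuracy=92.11]
IF rs445945 <= -0.3040 AND rs6712905 >= 0.1367 AND rs377954 <= -0.3691 THEN class = Homozygous deletion [support=3.23 accuracy=90.48]
IF rs6135314 <= -0.5109 AND rs6685801 <= -0.0057 AND rs2900712 <= -0.0619 AND rs9444675 <= 0.1020 THEN class = Homozygous deletion [support=4.61 accuracy=93.33]
IF rs6135362 <= -0.2468 AND rs2100272 >= 0.1398 AND rs700029 <= 0.0035 THEN class = Homozygous deletion [support=1.84 accuracy=91.67]
IF rs6110500 <= -0.2528 AND rs10500528 <= -0.0094 THEN class = Homozygous deletion [support=7.37 accuracy=83.33]
IF rs6079537 <= -0.2319 AND rs2900712 <= -0.0981 AND rs6043173 >= -0.0832 THEN class = Homozygous deletion [support=0.92 accuracy=100.00]
IF rs9355387 <= -0.2856 AND rs11905979 <= -0.3878 THEN class = Homozygous deletion [support=1.84 accuracy=91.67]
IF rs199305 <= -0.4455 AND rs377201 >= -0.2189 THEN class = Homozygous deletion [support=0.77 accuracy=100.00]
IF rs6135314 >= -0.0746 AND rs1998086 >= 0.0340 AND rs381053 >= -0.0576 THEN class = Wild-type [support=35.48 accuracy=98.70]
IF rs1475531 >= -0.0454 AND rs365516 >= 0.0220 THEN class = Wild-type [support=31.80 accuracy=96.14]
IF rs2423866 >= -0.1223 AND rs385770 >= -0.0670 AND rs7241111 >= -0.1500 THEN class = Wild-type [support=24.42 accuracy=98.11]
IF rs449849 >= -0.0559 AND rs716316 >= -0.0107 AND rs5904713 >= -0.1428 THEN class = Wild-type [support=27.80 accuracy=97.24]
IF rs1327323 <= -0.2719 AND rs6135269 <= -0.1044 THEN class = Wild-type [support=6.76 accuracy=75.00]
IF rs353149 >= -0.0059 AND rs13011654 >= 0.0742 AND rs445945 <= 0.067 THEN class = Wild-type [support=5.07 accuracy=96.97]
IF rs6034046 >= -0.015 AND rs6135314 >= -0.0323 AND rs6034011 <= 0.0668 THEN class = Wild-type [support=19.05 accuracy=95.16]
IF rs6043173 >= 0.131 AND rs449849 >= -0.0689 THEN class = Wild-type [support=23.81 accuracy=94.84]
OTHERS THEN class = Heterozygous deletion [support=20.28 accuracy=85.61]
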