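range_start,range_end,group_id
001,009,001-009
010,018,010-018
020,027,020-027
030,041,030-041
042,044,042-044
045,049,045-049
050,059,050-059
060,066,060-066
070,079,070-079
080,088,080-088
090,099,090-099
100,104,100-104
110,118,110-118
120,129,120-129
130,136,130-136
137,139,137-139
140,149,140-149
150,159,150-159
160,165,160-165
170,176,170-176
179,189,179-189
190,199,190-199
200,208,200-208
209,209,209-209
210,229,210-229
230,234,230-234
235,238,235-238
239,239,239-239
240,246,240-246
249,259,249-259
260,269,260-269
270,279,270-279
280,289,280-289
290,294,290-294
295,299,295-299
300,316,300-316
317,319,317-319
320,327,320-327
330,337,330-337
338,338,338-338
339,339,339-339
340,349,340-349
350,359,350-359
360,379,360-379
380,389,380-389
390,392,390-392
393,398,393-398
401,405,401-405
410,414,410-414
415,417,415-417
420,429,420-429
430,438,430-438
440,449,440-449
451,459,451-459
460,466,460-466
470,478,470-478
480,488,480-488
490,496,490-496
500,508,500-508
510,519,510-519
520,529,520-529
530,539,530-539
540,543,540-543
550,553,550-553
555,558,555-558
560,569,560-569
570,579,570-579
580,589,580-589
590,599,590-599
600,608,600-608
610,612,610-612
614,616,614-616
617,629,617-629
630,639,630-639
640,649,640-649
650,659,650-659
660,669,660-669
670,677,670-677
678,679,678-679
680,686,680-686
690,698,690-698
700,709,700-709
710,719,710-719
720,724,720-724
725,729,725-729
730,739,730-739
740,759,740-759
760,763,760-763
764,779,764-779
780,789,780-789
790,796,790-796
797,799,797-799
800,804,800-804
805,809,805-809
810,819,810-819
820,829,820-829
830,839,830-839
840,848,840-848
850,854,850-854
860,869,860-869
870,879,870-879
880,887,880-887
890,897,890-897
900,904,900-904
905,909,905-909
910,919,910-919
920,924,920-924
925,929,925-929
930,939,930-939
940,949,940-949
950,957,950-957
958,959,958-959
960,979,960-979
980,989,980-989
990,995,990-995
996,999,996-999
V01,V09,V01-V09
V10,V19,V10-V19
V20,V29,V20-V29
V30,V39,V30-V39
V40,V49,V40-V49
V50,V59,V50-V59
V60,V69,V60-V69
V70,V82,V70-V82
V83,V91,V83-V91
E800,E807,E800-E807
E810,E819,E810-E819
E820,E825,E820-E825
E826,E829,E826-E829
E830,E838,E830-E838
E840,E845,E840-E845
E846,E849,E846-E849
E850,E858,E850-E858
E860,E869,E860-E869
E870,E876,E870-E876
E878,E879,E878-E879
E880,E888,E880-E888
E890,E899,E890-E899
E900,E909,E900-E909
E910,E915,E910-E915
E916,E928,E916-E928
E929,E929,E929-E929
E930,E949,E930-E949
E950,E959,E950-E959
E960,E969,E960-E969
E970,E978,E970-E978
E980,E989,E980-E989
E990,E999,E990-E999
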