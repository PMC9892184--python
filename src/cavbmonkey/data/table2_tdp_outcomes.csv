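animal,month,outcome,vehicle,moxifloxacin,reablation
1,-1,no_tdp,0,0,0
1,1,no_tdp,0,0,0
1,2,no_tdp,0,0,0
1,3,no_tdp,0,0,0
1,4,no_tdp,0,0,0
1,5,no_tdp,0,0,0
1,6,nr,0,0,0
1,7,no_tdp,0,0,0
1,8,no_tdp,0,0,0
1,9,no_tdp,0,0,0
1,10,no_tdp,0,0,0
1,12,no_tdp,0,0,0
1,13,no_tdp,0,0,0
1,15,no_tdp,0,0,0
2,-1,no_tdp,0,0,0
2,1,tdp,0,0,0
2,2,tdp,0,0,0
2,3,tdp,0,0,0
2,4,tdp,0,0,0
2,5,no_tdp,1,0,0
2,6,tdp,0,1,0
2,7,nr,0,0,0
2,8,autopsy,0,0,0
2,9,not_done,0,0,0
2,10,not_done,0,0,0
2,12,not_done,0,0,0
2,13,not_done,0,0,0
2,15,not_done,0,0,0
3,-1,no_tdp,0,0,0
3,1,na,0,0,1
3,2,no_tdp,0,0,0
3,3,no_tdp,0,0,0
3,4,tdp,0,0,0
3,5,no_tdp,0,0,0
3,6,nr,0,0,0
3,7,tdp,0,0,0
3,8,tdp,0,0,0
3,9,no_tdp,1,1,0
3,10,nr,0,0,0
3,12,nr,0,0,0
3,13,nr,0,0,0
3,15,no_tdp,0,0,0
4,-1,no_tdp,0,0,0
4,1,no_tdp,0,0,0
4,2,no_tdp,0,0,0
4,3,na,0,0,1
4,4,no_tdp,0,0,0
4,5,no_tdp,0,0,0
4,6,nr,0,0,0
4,7,no_tdp,0,0,0
4,8,no_tdp,0,0,0
4,9,no_tdp,0,0,0
4,10,no_tdp,0,0,0
4,12,no_tdp,0,0,0
4,13,no_tdp,0,0,0
4,15,no_tdp,0,0,0
5,-1,no_tdp,0,0,0
5,1,no_tdp,0,0,0
5,2,no_tdp,0,0,0
5,3,no_tdp,0,0,0
5,4,no_tdp,0,0,0
5,5,no_tdp,0,0,0
5,6,nr,0,0,0
5,7,no_tdp,0,0,0
5,8,no_tdp,0,0,0
5,9,no_tdp,0,0,0
5,10,no_tdp,0,0,0
5,12,no_tdp,0,0,0
5,13,no_tdp,0,0,0
5,15,no_tdp,0,0,0
6,-1,no_tdp,0,0,0
6,1,no_tdp,0,0,0
6,2,no_tdp,0,0,0
6,3,no_tdp,0,0,0
6,4,no_tdp,0,0,0
6,5,no_tdp,0,0,0
6,6,nr,0,0,0
6,7,no_tdp,0,0,0
6,8,no_tdp,0,0,0
6,9,no_tdp,0,0,0
6,10,no_tdp,0,0,0
6,12,no_tdp,0,0,0
6,13,no_tdp,0,0,0
6,15,no_tdp,0,0,0
7,-1,no_tdp,0,0,0
7,1,no_tdp,0,0,0
7,2,no_tdp,0,0,0
7,3,no_tdp,0,0,0
7,4,no_tdp,0,0,0
7,5,no_tdp,0,0,0
7,6,nr,0,0,0
7,7,tdp,0,0,0
7,8,no_tdp,0,0,0
7,9,no_tdp,0,0,0
7,10,no_tdp,0,0,0
7,12,no_tdp,0,0,0
7,13,no_tdp,0,0,0
7,15,no_tdp,0,0,0
8,-1,no_tdp,0,0,0
8,1,no_tdp,0,0,0
8,2,no_tdp,0,0,0
8,3,no_tdp,0,0,0
8,4,tdp,0,0,0
8,5,tdp,0,0,0
8,6,tdp,0,1,0
8,7,no_tdp,1,0,0
8,8,autopsy,0,0,0
8,9,not_done,0,0,0
8,10,not_done,0,0,0
8,12,not_done,0,0,0
8,13,not_done,0,0,0
8,15,not_done,0,0,0
9,-1,no_tdp,0,0,0
9,1,no_tdp,0,0,0
9,2,no_tdp,0,0,0
9,3,no_tdp,0,0,0
9,4,no_tdp,0,0,0
9,5,no_tdp,0,0,0
9,6,nr,0,0,0
9,7,no_tdp,0,0,0
9,8,no_tdp,0,0,0
9,9,no_tdp,0,0,0
9,10,no_tdp,0,0,0
9,12,tdp,0,0,0
9,13,no_tdp,0,0,0
9,15,no_tdp,0,0,0
10,-1,no_tdp,0,0,0
10,1,no_tdp,0,0,0
10,2,tdp,0,0,0
10,3,no_tdp,0,0,0
10,4,no_tdp,0,0,0
10,5,na,0,0,1
10,6,nr,0,0,0
10,7,no_tdp,0,0,0
10,8,no_tdp,0,0,0
10,9,no_tdp,0,0,0
10,10,no_tdp,0,0,0
10,12,tdp,0,0,0
10,13,no_tdp,0,0,0
10,15,tdp,0,0,0
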