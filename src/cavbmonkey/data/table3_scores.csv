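animal,month,score,runs_ge3,tdp,status
1,-1,0.3,0,0,recorded
1,1,0.3,0,0,recorded
1,2,0.3,0,0,recorded
1,3,2.0,0,0,recorded
1,4,0.3,0,0,recorded
1,5,0.3,0,0,recorded
1,6,,0,0,nr
1,7,0.7,0,0,recorded
1,8,0.3,0,0,recorded
1,9,0.3,0,0,recorded
1,10,0.3,0,0,recorded
1,12,0.3,0,0,recorded
1,13,0.3,0,0,recorded
1,15,0.3,0,0,recorded
2,-1,0.3,0,0,recorded
2,1,13.0,0,1,recorded
2,2,26.3,0,1,recorded
2,3,32.7,0,1,recorded
2,4,30.7,0,1,recorded
2,5,,0,0,not_done
2,6,44.0,0,1,recorded
2,7,,0,0,nr
2,8,,0,0,not_done
2,9,,0,0,not_done
2,10,,0,0,not_done
2,12,,0,0,not_done
2,13,,0,0,not_done
2,15,,0,0,not_done
3,-1,0.3,0,0,recorded
3,1,,0,0,na
3,2,5.0,1,0,recorded
3,3,5.0,1,0,recorded
3,4,6.0,0,1,recorded
3,5,5.0,1,0,recorded
3,6,,0,0,nr
3,7,17.7,0,1,recorded
3,8,20.7,0,1,recorded
3,9,,0,0,not_done
3,10,,0,0,nr
3,12,,0,0,nr
3,13,,0,0,nr
3,15,5.0,1,0,recorded
4,-1,0.3,0,0,recorded
4,1,3.0,1,0,recorded
4,2,5.0,1,0,recorded
4,3,,0,0,na
4,4,2.3,0,0,recorded
4,5,2.0,0,0,recorded
4,6,,0,0,nr
4,7,0.3,0,0,recorded
4,8,0.7,0,0,recorded
4,9,2.0,0,0,recorded
4,10,3.7,1,0,recorded
4,12,2.0,0,0,recorded
4,13,2.0,0,0,recorded
4,15,2.0,0,0,recorded
5,-1,0.3,0,0,recorded
5,1,5.0,1,0,recorded
5,2,5.0,1,0,recorded
5,3,4.0,1,0,recorded
5,4,5.0,1,0,recorded
5,5,5.0,1,0,recorded
5,6,,0,0,nr
5,7,5.0,1,0,recorded
5,8,4.3,1,0,recorded
5,9,5.0,1,0,recorded
5,10,5.0,1,0,recorded
5,12,5.0,1,0,recorded
5,13,5.0,1,0,recorded
5,15,5.0,1,0,recorded
6,-1,0.3,0,0,recorded
6,1,3.0,1,0,recorded
6,2,0.3,0,0,recorded
6,3,2.3,0,0,recorded
6,4,2.7,0,0,recorded
6,5,2.0,0,0,recorded
6,6,,0,0,nr
6,7,2.7,0,0,recorded
6,8,2.0,0,0,recorded
6,9,3.0,1,0,recorded
6,10,3.0,1,0,recorded
6,12,3.0,1,0,recorded
6,13,3.0,1,0,recorded
6,15,3.0,1,0,recorded
7,-1,0.3,0,0,recorded
7,1,2.3,0,0,recorded
7,2,3.7,0,0,recorded
7,3,2.0,0,0,recorded
7,4,4.3,1,0,recorded
7,5,2.0,0,0,recorded
7,6,,0,0,nr
7,7,10.3,0,1,recorded
7,8,3.0,1,0,recorded
7,9,2.0,0,0,recorded
7,10,3.3,1,0,recorded
7,12,3.3,1,0,recorded
7,13,3.0,1,0,recorded
7,15,3.0,1,0,recorded
8,-1,0.3,0,0,recorded
8,1,4.0,1,0,recorded
8,2,2.3,0,0,recorded
8,3,3.0,1,0,recorded
8,4,30.7,0,1,recorded
8,5,6.0,0,1,recorded
8,6,30.7,0,1,recorded
8,7,,0,0,not_done
8,8,,0,0,not_done
8,9,,0,0,not_done
8,10,,0,0,not_done
8,12,,0,0,not_done
8,13,,0,0,not_done
8,15,,0,0,not_done
9,-1,0.3,0,0,recorded
9,1,5.0,1,0,recorded
9,2,4.3,1,0,recorded
9,3,5.0,1,0,recorded
9,4,3.0,1,0,recorded
9,5,5.0,1,0,recorded
9,6,,0,0,nr
9,7,5.0,1,0,recorded
9,8,3.0,1,0,recorded
9,9,5.0,1,0,recorded
9,10,5.0,1,0,recorded
9,12,9.3,0,1,recorded
9,13,5.0,1,0,recorded
9,15,5.0,1,0,recorded
10,-1,0.3,0,0,recorded
10,1,4.0,1,0,recorded
10,2,10.3,0,1,recorded
10,3,5.0,1,0,recorded
10,4,5.0,1,0,recorded
10,5,,0,0,na
10,6,,0,0,nr
10,7,2.0,0,0,recorded
10,8,2.0,0,0,recorded
10,9,5.0,1,0,recorded
10,10,5.0,1,0,recorded
10,12,9.7,0,1,recorded
10,13,5.0,1,0,recorded
10,15,8.7,0,1,recorded
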