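amine_id,dg_eq1,dg_eq2,dg_eq3,dg_eq4,dg_eq5,vbur_total
1,-0.3,22.8,24.0,13.8,3.9,49.8
2,-1.3,21.7,18.4,11.8,-12.7,25.2
3,-3.9,19.1,17.6,8.5,-9.1,39.4
4,-1.8,21.2,20.0,10.8,,36.5
5,-5.1,18.0,24.1,12.7,,48.0
6,-0.8,22.2,33.6,17.2,,55.8
7,4.2,27.2,35.0,17.4,,55.8
8,6.3,29.3,45.9,,,68.5
9,4.5,27.5,35.8,,,55.8
10,2.3,25.3,,,,63.3
11,-0.6,22.5,30.7,16.4,11.1,59.0
12,-5.3,17.8,23.5,13.4,,55.6
13,1.0,24.1,33.3,21.1,,55.0
14,-4.5,18.6,30.1,17.6,,61.6
15,-9.1,13.9,27.2,15.1,,56.2
16,-6.3,16.7,24.7,13.6,,54.0
17,-4.9,18.1,18.7,17.7,,59.3
18,-3.1,20.0,20.7,11.1,-5.8,43.3
19,-8.6,14.5,21.3,10.8,,51.9
20,-4.2,18.8,34.7,12.9,-2.4,46.2
21,-2.4,20.6,18.1,21.2,11.6,53.8
22,-3.3,19.8,19.4,10.5,-7.9,38.8
23,-2.1,20.9,31.8,9.7,-9.7,33.9
24,12.1,35.1,27.2,15.3,,43.8
25,13.2,36.2,34.8,13.1,-0.1,42.0
26,30.7,53.7,28.7,16.0,,38.6
27,10.0,33.0,27.0,13.5,,50.1
28,-8.4,14.6,32.9,14.1,,65.6
29,-4.5,18.6,27.5,18.1,,58.4
30,-5.5,17.5,30.7,,,61.0
31,-5.1,18.0,23.5,,,61.4
32,-6.5,16.5,,,,61.9
33,-3.7,19.4,32.2,19.5,,65.1
34,-7.0,16.1,31.0,,,68.2
35,-7.1,15.9,24.4,14.5,6.2,67.8
36,-6.2,16.8,,17.3,,70.3
37,-5.3,17.7,28.7,16.1,,63.6
38,-6.5,16.5,26.3,,8.0,67.4
39,-5.8,17.2,26.0,13.6,8.7,67.9
40,-5.6,17.4,,,,61.3
41,9.0,32.0,29.7,,,54.5
42,-7.9,15.2,25.4,13.3,,61.6
43,-3.4,19.6,,16.0,,63.1
NH3,8.4,31.4,20.7,11.0,-11.4,15.2
NMe3,-0.2,22.9,21.5,12.3,-7.0,29.7
NEt3,-3.2,19.8,21.0,11.2,0.4,44.8
Py,5.3,28.4,,,,21.3
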