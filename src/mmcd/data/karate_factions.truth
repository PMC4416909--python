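# Two-faction split after the club dispute (instructor vs administrator).
# Individual 9 is listed with the administrator faction, the assignment
# used as ground truth throughout the community-detection literature.
1 Mr._Hi
2 Mr._Hi
3 Mr._Hi
4 Mr._Hi
5 Mr._Hi
6 Mr._Hi
7 Mr._Hi
8 Mr._Hi
9 Officer
10 Officer
11 Mr._Hi
12 Mr._Hi
13 Mr._Hi
14 Mr._Hi
15 Officer
16 Officer
17 Mr._Hi
18 Mr._Hi
19 Officer
20 Mr._Hi
21 Officer
22 Mr._Hi
23 Officer
24 Officer
25 Officer
26 Officer
27 Officer
28 Officer
29 Officer
30 Officer
31 Officer
32 Officer
33 Officer
34 Officer
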