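group_id	LPS	pH	INT
1	0	+	0
2	0	-	0
3	+	0	0
4	-	0	0
5	+	+	0
6	+	-	0
7	-	+	0
8	-	-	0
9	+	0	-
10	+	+	-
11	+	-	-
12	-	0	+
13	-	+	+
14	-	-	+
15	+	0	+
16	+	+	+
17	+	-	+
18	-	0	-
19	0	0	+
20	0	0	-
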