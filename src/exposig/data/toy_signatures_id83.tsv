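Type	background	exposure
1:Del:C:0	0	0.1
1:Del:C:1	0.2	0.4
1:Del:C:2	0	0.3
1:Del:C:3	0	0.15
1:Del:C:4	0	0
1:Del:C:5	0	0
1:Del:T:0	0	0
1:Del:T:1	0	0.05
1:Del:T:2	0	0
1:Del:T:3	0.3	0
1:Del:T:4	0.2	0
1:Del:T:5	0	0
1:Ins:C:0	0	0
1:Ins:C:1	0.15	0
1:Ins:C:2	0	0
1:Ins:C:3	0	0
1:Ins:C:4	0	0
1:Ins:C:5	0	0
1:Ins:T:0	0	0
1:Ins:T:1	0	0
1:Ins:T:2	0	0
1:Ins:T:3	0.15	0
1:Ins:T:4	0	0
1:Ins:T:5	0	0
2:Del:R:0	0	0
2:Del:R:1	0	0
2:Del:R:2	0	0
2:Del:R:3	0	0
2:Del:R:4	0	0
2:Del:R:5	0	0
3:Del:R:0	0	0
3:Del:R:1	0	0
3:Del:R:2	0	0
3:Del:R:3	0	0
3:Del:R:4	0	0
3:Del:R:5	0	0
4:Del:R:0	0	0
4:Del:R:1	0	0
4:Del:R:2	0	0
4:Del:R:3	0	0
4:Del:R:4	0	0
4:Del:R:5	0	0
5:Del:R:0	0	0
5:Del:R:1	0	0
5:Del:R:2	0	0
5:Del:R:3	0	0
5:Del:R:4	0	0
5:Del:R:5	0	0
2:Ins:R:0	0	0
2:Ins:R:1	0	0
2:Ins:R:2	0	0
2:Ins:R:3	0	0
2:Ins:R:4	0	0
2:Ins:R:5	0	0
3:Ins:R:0	0	0
3:Ins:R:1	0	0
3:Ins:R:2	0	0
3:Ins:R:3	0	0
3:Ins:R:4	0	0
3:Ins:R:5	0	0
4:Ins:R:0	0	0
4:Ins:R:1	0	0
4:Ins:R:2	0	0
4:Ins:R:3	0	0
4:Ins:R:4	0	0
4:Ins:R:5	0	0
5:Ins:R:0	0	0
5:Ins:R:1	0	0
5:Ins:R:2	0	0
5:Ins:R:3	0	0
5:Ins:R:4	0	0
5:Ins:R:5	0	0
2:Del:M:1	0	0
3:Del:M:1	0	0
3:Del:M:2	0	0
4:Del:M:1	0	0
4:Del:M:2	0	0
4:Del:M:3	0	0
5:Del:M:1	0	0
5:Del:M:2	0	0
5:Del:M:3	0	0
5:Del:M:4	0	0
5:Del:M:5	0	0
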