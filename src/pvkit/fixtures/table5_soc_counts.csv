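rank,soc,n
1,skin and appendages disorders,13295
2,body as a whole-general disorders,3886
3,gastro-intestinal system disorders,1703
4,respiratory system disorders,536
5,autonomic nervous system disorders,515
6,central and peripheral nervous system disorders,257
7,urinary system disorders,151
8,psychiatric disorders,105
9,metabolic and nutritional disorders,90
10,vision disorders,53
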