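pair,lexical,syntactic,semantic,combined
"(1, 2)",0.389,0.387,0.48718,0.437091
"(1, 3)",0.269,0.369,0.366129,0.332715
"(1, 4)",0.43,0.392,0.632559,0.523859
"(1, 5)",0.25,0.411,0.423508,0.361027
"(1, 6)",0.407,0.323,0.364275,0.372641
"(1, 7)",0.278,0.302,0.501854,0.39217
"(1, 8)",0.239,0.295,0.388685,0.321664
"(1, 9)",0.222,0.354,0.560764,0.409917
"(2, 3)",0.282,0.273,0.24187,0.260789
"(2, 4)",0.505,0.363,0.561909,0.510588
"(2, 5)",0.619,0.541,0.651628,0.622744
"(2, 6)",0.457,0.428,0.584822,0.515434
"(2, 7)",0.544,0.347,0.540378,0.51104
"(2, 8)",0.3,0.283,0.461771,0.377072
"(2, 9)",0.381,0.481,0.519009,0.46487
"(3, 4)",0.361,0.379,0.402077,0.384101
"(3, 5)",0.344,0.29,0.179868,0.254529
"(3, 6)",0.25,0.325,0.250725,0.262226
"(3, 7)",0.339,0.285,0.133236,0.229002
"(3, 8)",0.389,0.274,0.321337,0.33744
"(3, 9)",0.362,0.327,0.249352,0.30092
"(4, 5)",0.492,0.361,0.643518,0.545976
"(4, 6)",0.37,0.357,0.576413,0.469715
"(4, 7)",0.583,0.378,0.592837,0.55541
"(4, 8)",0.332,0.297,0.317247,0.319187
"(4, 9)",0.361,0.433,0.497243,0.439569
"(5, 6)",0.324,0.411,0.545229,0.446845
"(5, 7)",0.583,0.448,0.623993,0.581849
"(5, 8)",0.355,0.245,0.286773,0.303953
"(5, 9)",0.49,0.349,0.465048,0.455385
"(6, 7)",0.38,0.358,0.459003,0.415472
"(6, 8)",0.231,0.305,0.356927,0.304799
"(6, 9)",0.241,0.426,0.453879,0.375236
"(7, 8)",0.329,0.26,0.285388,0.296578
"(7, 9)",0.444,0.369,0.58874,0.503496
"(8, 9)",0.362,0.271,0.579831,0.455002
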