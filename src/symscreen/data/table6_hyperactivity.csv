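pair,lexical,syntactic,semantic,combined
"(1, 2)",0.497,0.378,0.49817,0.492961
"(1, 3)",0.302,0.361,0.342444,0.334745
"(1, 4)",0.361,0.332,0.362818,0.361164
"(1, 5)",0.321,0.339,0.210753,0.239127
"(1, 6)",0.202,0.307,0.186174,0.194478
"(1, 7)",0.249,0.286,0.171612,0.192536
"(1, 8)",0.255,0.364,0.299014,0.292486
"(1, 9)",0.257,0.311,0.328696,0.312958
"(2, 3)",0.44,0.394,0.256771,0.300792
"(2, 4)",0.383,0.377,0.379405,0.380058
"(2, 5)",0.345,0.375,0.182809,0.224698
"(2, 6)",0.238,0.375,0.139689,0.169988
"(2, 7)",0.307,0.33,0.199761,0.227588
"(2, 8)",0.405,0.378,0.398189,0.39878
"(2, 9)",0.243,0.319,0.316006,0.300849
"(3, 4)",0.417,0.433,0.331869,0.353866
"(3, 5)",0.545,0.417,0.282405,0.34293
"(3, 6)",0.3,0.342,0.329678,0.323975
"(3, 7)",0.424,0.314,0.174931,0.232809
"(3, 8)",0.433,0.364,0.24489,0.289185
"(3, 9)",0.353,0.319,0.286514,0.301772
"(4, 5)",0.429,0.406,0.066521,0.156417
"(4, 6)",0.219,0.342,0.059587,0.104622
"(4, 7)",0.362,0.329,0.114622,0.175258
"(4, 8)",0.369,0.417,0.34614,0.353852
"(4, 9)",0.27,0.351,0.326678,0.315819
"(5, 6)",0.317,0.338,0.240915,0.260851
"(5, 7)",0.402,0.32,0.037393,0.125385
"(5, 8)",0.529,0.406,0.105811,0.206791
"(5, 9)",0.459,0.417,0.233903,0.288583
"(6, 7)",0.367,0.363,0.310563,0.324542
"(6, 8)",0.375,0.338,0.119194,0.181777
"(6, 9)",0.375,0.327,0.422799,0.408836
"(7, 8)",0.36,0.307,0.335182,0.339213
"(7, 9)",0.376,0.309,0.324902,0.33494
"(8, 9)",0.465,0.321,0.377193,0.39325
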