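subject;T1_MC;T1_SC;T2_MC;T2_SC;T3_MC;T3_SC;T4_MC;T4_SC
H1;73,6;81,9;77,3;84,1;73,9;84,5;79,6;84,5
H2;73,3;81,2;77,5;86,5;86,6;91,8;78,6;91,9
H3;71,2;74,6;76,9;76,8;71,8;76;76,1;75
H4;85,9;87;80,8;89;86,3;86,7;89,4;94,1
H5;81,2;77,6;91,3;79,12;81;77,6;87,4;84,6
H6;76,4;79,6;83,1;80,6;81,9;79,8;78,2;73,1
H7;95,1;87,6;86,9;81,7;89;88,1;93,1;83,5
H8;70,1;75,8;83,6;68,9;76,1;77,9;83,5;76,7
H9;77,3;86,1;75,7;72,4;70,3;82;80,7;92
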