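subject;T1_MC;T1_SC;T2_MC;T2_SC;T3_MC;T3_SC;T4_MC;T4_SC
P1;73,5;72,6;73;78,4;78,3;81,7;77,9;81
P2;60,3;71,3;81,3;76,1;74,2;71,4;70,8;75,2
P3;63,4;69,2;90,9;69;80,6;70,5;87,2;74,1
P4;65;74,9;69,5;73,4;61,6;74,9;75,3;73,5
P5;80,2;78,8;80,6;70,6;89;83,7;82,1;82
P6;80,9;78,6;81,3;86,2;86,4;89,3;88,7;85,2
P7;72,9;80,7;76,2;75,4;74,7;79,2;72,7;80,1
P8;76,6;86,1;78,6;83,7;80,6;76,7;76,3;83,7
P9;80,4;78,6;78,4;90,2;79,1;88,7;84,4;83,9
P10;82,2;76,2;77,9;79;80,1;85,6;79,4;87,5
P11;82;72,3;78,8;78,5;74,7;76,5;85,2;69,7
P12;79,1;76,5;85,7;75,5;70,7;81,5;79,3;77
P13;77,6;77,6;86,4;86,3;88,4;83,1;91;96,7
P14;75,9;72,9;79;74;85,4;83,2;77,2;81,5
P15;67;87,5;79;95,1;79,2;90,7;80,3;89,7
P16;61,5;63,9;56,4;74,8;79,4;78,4;76,8;83,7
P17;70,6;70,4;75,3;76,6;80;74,2;71,4;70,9
P18;66,4;70,3;74,6;74,8;80,9;79,5;78;80
P19;78,1;82,5;88,8;85,3;84,3;85,9;69,6;84,9
P20;72,9;72,4;77,5;70;86,4;76,8;78,9;74,1
P21;72,7;72,3;69,5;76,9;75,5;82,9;77,4;79,3
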