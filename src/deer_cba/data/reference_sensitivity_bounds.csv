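strategy,column,value,verified
1,lower_meat,-267488,True
1,lower_recreational,-746745,True
1,lower_browsing,709104,True
1,lower_traffic,313798,True
1,benchmark,2477,True
1,upper_meat,272442,True
1,upper_recreational,751699,True
1,upper_browsing,-704150,True
1,upper_traffic,-308844,True
2,lower_meat,-1183000,False
2,lower_recreational,-1506899,False
2,lower_browsing,-228352,False
2,lower_traffic,-674963,False
2,benchmark,-1024737,True
2,upper_meat,-870094,False
2,upper_recreational,-546595,False
2,upper_browsing,-1825142,False
2,upper_traffic,-1378531,False
3,lower_meat,27023,False
3,lower_recreational,-667007,False
3,lower_browsing,1067159,False
3,lower_traffic,640872,False
3,benchmark,296684,False
3,upper_meat,583290,False
3,upper_recreational,1277320,False
3,upper_browsing,-456846,False
3,upper_traffic,-30559,False
4A,lower_meat,-434209,True
4A,lower_recreational,-917002,True
4A,lower_browsing,558439,True
4A,lower_traffic,142029,True
4A,benchmark,-185927,True
4A,upper_meat,62356,True
4A,upper_recreational,545148,True
4A,upper_browsing,-930292,True
4A,upper_traffic,-513882,True
4B,lower_meat,-539705,True
4B,lower_recreational,-1002252,True
4B,lower_browsing,450794,True
4B,lower_traffic,28818,True
4B,benchmark,-303527,True
4B,upper_meat,-67349,True
4B,upper_recreational,395198,True
4B,upper_browsing,-1057848,True
4B,upper_traffic,-635872,True
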