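strategy,meat_total,recreational_total,browsing_total,traffic_total,net_benefit
1,539930,1498444,1413255,622642,2477
2,313982,961638,1596790,703567,-1024737
3,554301,1939820,1524006,671431,296684
4A,496565,1462150,1488731,655911,-185927
4B,472355,1397450,1508643,664690,-303527
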