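gene	BA15_vs_BA0	BA120_vs_BA0
AT5G62920	4,83	3,08
AT3G44326	2,44	2,42
AT4G29740	7,60	6,29
AT1G19050	11,72	8,94
AT5G47980	2,00	12,29
AT1G68360	3,02	2,51
AT5G19110	2,01	4,48
AT2G40670	2,39	7,51
AT4G29690	2,10	6,76
AT4G23750	2,01	2,58
AT4G37410	2,63	7,58
AT4G29700	2,26	4,56
AT2G01890	2,12	3,12
AT1G17190	2,50	3,33
AT2G41310	2,68	4,50
AT4G24190	2,08	2,91
AT1G50280	5,76	9,11
AT1G53060	2,12	16,16
AT1G28100	2,83	3,80
AT3G58990	3,86	2,22
AT5G66210	2,71	2,13
AT1G18800	2,28	2,54
AT5G41590	2,13	2,18
AT3G18773	4,20	4,19
AT5G08640	3,80	6,57
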