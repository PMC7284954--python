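isolate_id	lineage_of_origin	mean_di_australis	mean_di_americanus
USGS23	americanus	6.6	5.8
USGS32	australis	3.7	4.1
USGS30	australis	3.5	2.2
LSU0038	americanus	3.2	3.1
USGS15	australis	2.9	2.5
USGS17	americanus	2.6	2.9
LSU0361	gulf	2.6	1.6
LSU0719	australis	1.2	1.6
LSU0107	australis	0.2
LSU0172	australis	2.9	2.9
USGS07	americanus	1.7	2.8
LSU1247	gulf	3.6	3.8
USGS34	australis	3.1	2.3
USGS42	australis	0.3	2.8
LSU0677	gulf	4.6	3.7
USGS02	australis	2.2	1.3
LSU0240	americanus	2.3	2.5
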