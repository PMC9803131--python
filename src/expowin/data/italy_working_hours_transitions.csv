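sex,origin,h0,h1,h2,h3,h4,h5
both,h0,65.8 (59.2-72.3),8.9 (8.0-10.0),11.1 (10.0-12.2),7.6 (6.8-8.31),3.2 (2.8-3.5),5.1 (4.6-5.6)
both,h1,29.5 (26.5-32.4),41.3 (37.1-45.4),15.8 (14.2-17.3),8.1 (7.3-9.0),3.2 (2.9-3.5),5.2 (4.7-5.8)
both,h2,23.4 (21.1-25.8),9.2 (8.3-10.2),48.9 (44.1-53.8),11.6 (10.5-12.8),4.0 (3.6-4.4),5.7 (5.1-6.2)
both,h3,23.0 (20.7-25.3),8.6 (7.7-9.4),22.6 (20.4-24.9),37.2 (33.4-40.9),6.9 (6.2-7.6),8.3 (7.5-9.1)
both,h4,24.1 (21.7-26.6),9.6 (8.7-10.6),19.8 (17.8-21.8),17.3 (15.6-19.1),28.0 (25.2-30.8),14.3 (12.8-15.7)
both,h5,24.3 (21.9-26.8),8.5 (7.7-9.4),15.7 (14.2-17.3),13.0 (11.7-14.3),10.1 (9.1-11.1),36.9 (33.2-40.6)
female,h0,70.8 (63.8-77.8),9.6 (8.7-10.6),9.3 (8.4-10.2),5.8 (5.2-6.4),2.2 (2.0-2.4),3.2 (2.9-3.6)
female,h1,33.0 (29.7-36.3),45.1 (40.6-49.6),13.4 (12.1-14.7),5.8 (5.2-6.3),2.2 (2.0-2.4),3.3 (3.0-3.6)
female,h2,27.1 (24.4-29.8),10.8 (9.7-11.9),48.4 (43.6-53.3),10.3 (9.2-11.3),3.0 (2.7-3.3),4.5 (4.0-4.9)
female,h3,26.4 (23.8-29.1),10.7 (9.6-11.8),22.9 (20.6-25.2),36.3 (32.7-40.0),6.1 (5.5-6.7),7.3 (6.6-8.0)
female,h4,29.0 (26.1-31.9),12.1 (10.9-13.3),20.3 (18.3-22.2),17.2 (15.5-18.9),27.2 (24.5-29.9),13.6 (12.2-14.9)
female,h5,29.5 (26.6-32.5),10.5 (9.4-11.5),16.5 (14.8-18.1),12.4 (11.1-13.6),9.6 (8.7-10.6),34.3 (30.7-37.5)
male,h0,60.5 (54.4-66.5),8.1 (7.3-8.9),13.0 (11.7-14.3),9.4 (8.4-10.3),4.2 (3.8-4.6),7.0 (6.3-7.7)
male,h1,25.7 (23.2-28.3),37.2 (33.5-41.0),18.2 (16.4-20.1),10.6 (9.6-11.7),4.3 (3.8-4.7),7.3 (6.6-8.0)
male,h2,19.6 (17.6-21.6),7.6 (6.9-8.4),49.5 (44.5-54.4),13.1 (11.8-14.4),5.1 (4.6-5.6),6.9 (6.2-7.6)
male,h3,19.5 (17.5-21.4),6.3 (5.7-6.9),22.4 (20.1-24.6),38.0 (34.2-41.8),7.8 (7.0-8.6),9.4 (8.5-10.4)
male,h4,19.0 (17.1-20.9),7.1 (6.4-7.8),19.3 (17.4-21.2),17.4 (15.7-19.2),28.8 (25.9-31.6),15.0 (13.5-16.5)
male,h5,18.9 (17.0-20.8),6.5 (5.8-7.1),15.0 (13.5-16.5),13.6 (12.3-15.0),10.6 (9.5-11.6),39.8 (35.8-43.8)
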