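# provenance: synthetic corpus, 60 structures, seed 2024; see flexscore.synthdata.build_reference_distribution
rho	rmsd
-0.9442848310438942	0.0688601109870681
-0.9427180521622872	0.07435569528346492
-0.9359119187433537	0.07620185076041373
-0.9299566960966613	0.07817547339664155
-0.8894451728100379	0.0792207415100984
-0.8699146339260662	0.08059610301306197
-0.8408538366658859	0.08272429878362483
-0.810644301371428	0.08503811248190211
-0.8068245137083454	0.08633474763505868
-0.8001286912501832	0.08661156330213302
-0.7984941977043992	0.08711551880695845
-0.52614380543982	0.08783575440285059
0.0	0.0890911070337795
0.18317198197282408	0.08912521585224488
0.2759595522288177	0.09617625355487928
0.32597488208924363	0.09805317675058214
0.3445635909758107	0.10451782797699481
0.48946306347442353	0.10602966467365892
0.5176676733366868	0.10836526050874712
0.5278409305687054	0.11175427782689366
0.5308573781852238	0.11199689930163914
0.5480285285691531	0.11344853707802738
0.585724497107575	0.11622902243880691
0.6059927904140983	0.11897436520343825
0.6095115793112804	0.12781551904340116
0.6295826442928676	0.13007016648534805
0.6511520352470742	0.13038970451933612
0.6738288975233723	0.13289206034658768
0.6936073177936293	0.1368149704856519
0.7046783725757167	0.13755314690415804
0.7198276529456393	0.1413143598473496
0.7347352253266582	0.1413677593315262
0.7469996348428916	0.1434087769584865
0.7679680825919273	0.14430378233926883
0.777793629478889	0.14921466984555068
0.7887641970433772	0.15773384860318135
0.7901547447148504	0.16553990063075982
0.8035507912590106	0.1660693922959159
0.8078805026169261	0.17007013360585668
0.8107967096306115	0.17188898371208344
0.8119771578788808	0.18046098166122873
0.8331278662521058	0.1806919972452545
0.8374179240556349	0.1814438127484476
0.8393267814197225	0.1845791083063319
0.8487491423055253	0.1886746148163947
0.8530102339034209	0.19190589254462634
0.8565662271229451	0.19220025047029965
0.8572589367078987	0.19837902913931432
0.8620430719205796	0.2724476907833744
0.8668893538163139	0.3164807352580886
0.8730457672870748	0.3338611049225772
0.8823690588101415	0.3377352538650757
0.8898123288078081	0.338525160664724
0.8927707260258074	0.34995522765171777
0.8995528902176073	0.3524672297143256
0.9070698984707538	0.35276710502446645
0.9129744517881172	0.35704451093912326
0.9245227953752445	0.3656009527819012
0.9255416980471304	0.3690682450557529
0.9278437526783173	0.37268769446176053
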