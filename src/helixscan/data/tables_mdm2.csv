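table,section,name,notation,helicity_pct,ec50_uM,kd_nM,ratio_printed,parent_name
1,A,MP-292,Ac-LTF[R8]EYWQL[Cba][S5]SAA-amide,32.8,0.54,18.6,29,
1,A,L1A,Ac-ATF[R8]EYWQL[Cba][S5]SAA-amide,53.3,0.50,17.6,28,MP-292
1,A,T2A,Ac-LAF[R8]EYWQL[Cba][S5]SAA-amide,36.2,1.0,21.3,47,MP-292
1,A,F3A,Ac-LTA[R8]EYWQL[Cba][S5]SAA-amide,48.4,37,3600,10,MP-292
1,A,E5A,Ac-LTF[R8]AYWQL[Cba][S5]SAA-amide,27.6,0.18,29.8,6,MP-292
1,A,Y6A,Ac-LTF[R8]EAWQL[Cba][S5]SAA-amide,50.3,0.55,38.9,14,MP-292
1,A,W7A,Ac-LTF[R8]EYAQL[Cba][S5]SAA-amide,ND,8.8,5093,2,MP-292
1,A,Q8A,Ac-LTF[R8]EYWAL[Cba][S5]SAA-amide,33.4,0.10,26.5,4,MP-292
1,A,L9A,Ac-LTF[R8]EYWQA[Cba][S5]SAA-amide,48.7,0.16,12.0,13,MP-292
1,A,Cba10A,Ac-LTF[R8]EYWQLA[S5]SAA-amide,ND,11,176,61,MP-292
1,A,S12A,Ac-LTF[R8]EYWQL[Cba][S5]AAA-amide,36.5,0.35,20.4,17,MP-292
1,B,L1(D-Leu),Ac-[D-L]TF[R8]EYWQL[Cba][S5]SAA-amide,44.1,0.6,31,18,MP-292
1,B,T2(D-Thr),Ac-L[D-T]F[R8]EYWQL[Cba][S5]SAA-amide,40.7,3.4,136,25,MP-292
1,B,F3(D-Phe),Ac-LT[D-F][R8]EYWQL[Cba][S5]SAA-amide,51.8,>50,6485,>8,MP-292
1,B,E5(D-Glu),Ac-LTF[R8][D-E]YWQL[Cba][S5]SAA-amide,38.2,1.0,32,30,MP-292
1,B,Y6(D-Tyr),Ac-LTF[R8]E[D-Y]WQL[Cba][S5]SAA-amide,43.2,3.2,286,11,MP-292
1,B,W6(D-Trp) (MP-384),Ac-LTF[R8]EY[D-W]QL[Cba][S5]SAA-amide,41.0,0.6,30,20,MP-292
1,B,Q8(D-Gln),Ac-LTF[R8]EYW[D-Q]L[Cba][S5]SAA-amide,27.1,2.1,22,95,MP-292
1,B,L9(D-Leu),Ac-LTF[R8]EYWQ[D-L][Cba][S5]SAA-amide,39.0,1.1,30,37,MP-292
1,B,Cba10(D-Cba),Ac-LTF[R8]EYWQL[D-Cba][S5]SAA-amide,ND,8.1,1650,5,MP-292
1,B,S12(D-Ser),Ac-LTF[R8]EYWQL[Cba][S5][D-S]AA-amide,41.2,1.2,8.6,140,MP-292
1,B,A13(D-Ala),Ac-LTF[R8]EYWQL[Cba][S5]S[D-A]A-amide,41.8,0.6,17,35,MP-292
1,B,A14(D-Ala),Ac-LTF[R8]EYWQL[Cba][S5]SA[D-A]-amide,34.6,0.5,18,28,MP-292
1,C,Linear Parent (MP-189),Ac-LTF[Aib]EYWQL[Cba][Aib]SAA-amide,35.3,33.5,43.1,777,MP-292
1,C,Linear L1(D-Leu),Ac-[D-L]TF[Aib]EYWQL[Cba][Aib]SAA-amide,37.2,>50,277,>180,Linear Parent (MP-189)
1,C,Linear E5(D-Glu),Ac-LTF[Aib][D-E]YWQL[Cba][Aib]SAA-amide,21.4,>50,135,>370,Linear Parent (MP-189)
1,C,Linear Q8(D-Gln),Ac-LTF[Aib]EYW[D-Q]L[Cba][Aib]SAA-amide,21.8,>50,119,>370,Linear Parent (MP-189)
1,C,Linear L9(D-Leu),Ac-LTF[Aib]EYWQ[D-L][Cba][Aib]SAA-amide,19.7,>50,88,>568,Linear Parent (MP-189)
2,table2,MP-081,Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5]SAA-amide,49.6,0.42,19.0,22,
2,table2,L1(Aib),Ac-K(N3)-(βA)-[Aib]TF[R8]EYWAQ[Cba][S5]SAA-amide,42.7,0.49,29.5,17,MP-081
2,table2,T2(Aib),Ac-K(N3)-(βA)-L[Aib]F[R8]EYWAQ[Cba][S5]SAA-amide,38.3,2.9,1706,2,MP-081
2,table2,A8(Aib),Ac-K(N3)-(βA)-LTF[R8]EYW[Aib]Q[Cba][S5]SAA-amide,37.5,1.5,119.4,12,MP-081
2,table2,Q9(Aib),Ac-K(N3)-(βA)-LTF[R8]EYWA[Aib][Cba][S5]SAA-amide,28,0.25,33.1,8,MP-081
2,table2,S12(Aib),Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5][Aib]AA-amide,37.3,0.25,24.4,10,MP-081
2,table2,A13(Aib),Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5]A[Aib]A-amide,34.4,0.59,25.7,23,MP-081
2,table2,L1(N-methyl L-Leu),Ac-K(N3)-(βA)-[NMe-L]TF[R8]EYWAQ[Cba][S5]SAA-amide,32.6,0.46,23.5,20,MP-081
2,table2,L1(N-methyl L-Ala),Ac-K(N3)-(βA)-[NMe-A]TF[R8]EYWAQ[Cba][S5]SAA-amide,47.2,1.49,15.4,97,MP-081
2,table2,T2(N-methyl L-Thr),Ac-K(N3)-(βA)-L[NMe-T]F[R8]EYWAQ[Cba][S5]SAA-amide,38.2,7.7,352.2,22,MP-081
2,table2,A8(N-methyl L-Ala),Ac-K(N3)-(βA)-LTF[R8]EYW[NMe-A]Q[Cba][S5]SAA-amide,16.9,>50,671.3,>75,MP-081
2,table2,Q9(N-methyl L-Gln),Ac-K(N3)-(βA)-LTF[R8]EYWA[NMe-Q][Cba][S5]SAA-amide,20.2,>50,211.2,>237,MP-081
2,table2,A13(N-methyl L-Ala),Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5]S[NMe-A]A-amide,38.6,1.6,10.0,158,MP-081
2,table2,A14(N-methyl L-Ala),Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5]SA[NMe-A]-amide,47.5,0.71,5.9,120,MP-081
2,table2,L1P,Ac-K(N3)-(βA)-PTF[R8]EYWAQ[Cba][S5]SAA-amide,41.6,0.75,21.9,34,MP-081
2,table2,Q9P,Ac-K(N3)-(βA)-LTF[R8]EYWAP[Cba][S5]SAA-amide,27.4,3.1,77.1,41,MP-081
2,table2,S12P,Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5]PAA-amide,30.8,3.7,45.7,80,MP-081
2,table2,L1G,Ac-K(N3)-(βA)-GTF[R8]EYWAQ[Cba][S5]SAA-amide,44.6,1.6,22.1,73,MP-081
2,table2,E5G,Ac-K(N3)-(βA)-LTF[R8]GYWAQ[Cba][S5]SAA-amide,28.6,0.26,61.8,4,MP-081
2,table2,Q9G,Ac-K(N3)-(βA)-LTF[R8]EYWAG[Cba][S5]SAA-amide,38.8,0.68,42.0,16,MP-081
2,table2,S12G,Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5]GAA-amide,46.5,0.65,18.9,34,MP-081
2,table2,"L1G, E5G, A8G",Ac-K(N3)-(βA)-GTF[R8]GYWGQ[Cba][S5]SAA-amide,20.4,1.7,49.8,34,MP-081
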