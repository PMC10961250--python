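index,abbreviation,description,tissue
1,mca,Most anterior point on the tip of Meckel's cartilage,MC
2,mcsym,Most posteriosuperior point on the symphysis of Meckel's cartilage,MC
3,mcpl,Most posterior point on the left arm of Meckel's cartilage,MC
4,mcppl,Most inferior point on the posterior aspect of the left arm of Meckel's cartilage,MC
5,mcpr,Most posterior point on the right arm of Meckel's cartilage,MC
6,mcppr,Most inferior point on the posterior aspect of the right arm of Meckel's cartilage,MC
7,asep,Most anterior point of the nasal septum,C
8,psep,Intersection of the superoposterior aspect of the nasal septum with the nasal capsule,C
9,lppi,Most lateral point on the prominent pars intermedia (nasal capsule) on the left side,C
10,rppi,Most lateral point on the prominent pars intermedia (nasal capsule) on the right side,C
11,nct,Most posterior midpoint at which the left and right nasal capsule connects with the trabecular cartilage,C
12,lncse,Most superior anterior point where the nasal capsule (pars intermedia) intersects with the sphenethmoid commissure on the left side,C
13,lao,Most superolateral point on the ala orbitalis on the left side,C
14,laottr,Most superior point of the intersection of the ala orbitalis and tectum transversum on the left side,C
15,lttr,Most superior point on the tectum transversum on the left side,C
16,lttrpp,Most superior point on the intersection of the tectum transversum and the parietal plate on the left side,C
17,llpca,Most lateral point on the pars canalicularis on the left side,C
18,ltpoa,Intersection of the tectum posterius and occipital arch on the foramen magnum on the left side,C
19,rncse,Most superior anterior point where the nasal capsule (pars intermedia) intersects with the sphenethmoid commissure on the right side,C
20,rao,Most superolateral point on the ala orbitalis on the right side,C
21,raottr,Most superior point of the intersection of the ala orbitalis and tectum transversum on the right side,C
22,rttr,Most superior point on the tectum transversum on the right side,C
23,rttrpp,Most superior point on the intersection of the tectum transversum and the parietal plate on the right side,C
24,rlpca,Most lateral point on the pars canalicularis on the right side,C
25,rtpoa,Intersection of the tectum posterius and occipital arch on the foramen magnum on the right side,C
26,llat,Most lateral point on the ala temporalis on the left side,C
27,rlat,Most lateral point on the ala temporalis on the right side,C
28,lcsp,Intersection of the sphenocochlear commissure and pars cochlearis on the left side,C
29,rcsp,Intersection of the sphenocochlear commissure and pars cochlearis on the right side,C
30,laioc,Most posterior inferior point on the occipital condyle on the left side,C
31,raioc,Most posterior inferior point on the occipital condyle on the right side,C
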