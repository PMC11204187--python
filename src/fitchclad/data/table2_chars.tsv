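1	ScA crosses the subcostal area: 0, no; 1, yes.
2	ScP redirected anterior margin near the tegmen apex: 0, no; 1, yes.
3	Area between RP and MA with a distinct oblique vein separating two sets of cross veins: 0, no; 1, yes, oblique vein connected to the middle of the free RP; 2, yes, connected to the base of the free RP; 3, no distinct oblique vein but several long curved cross veins.
4	Base of the RP far away from the base of the MA: 0, no, close to each other; 1, yes.
5	RP: 0, curved toward the posterior margin; 1, basally curved toward the posterior margin then redirected to the anterior wing margin; 2, curved toward the anterior margin.
6	RP branched: 0, distally; 1, basally.
7	R forks into RA and RP: 0, distal of 3/5 of the wing; 1, closer to the middle than to 3/5 of the wing.
8	Area between RA and RP: 0, lancet-like; 1, rectangular.
9	MP basally curved: no (...); 0, 1, yes. [state listing printed garbled; stored verbatim, matrix taken as authoritative]
10	Free CuA three times in length longer than free M: 0, no; 1, yes.
11	MA: 0, undulate; 1, arch; 2, obliquely straight.
12	Widest part of the area between R and MA located: 0, at or after the forking of M and before the forking of R; 1, at the forking of R; 2, after the forking of R.
13	MP: 0, sigmoidal (base curved to the posterior wing margin); 1, straight; 2, bowed toward the posterior wing margin.
14	CuA separated from M + CuA: 0, close to 1/3 of the wing length; 1, distal to 2/5 of the wing length.
15	Part of MA opposite RP: 0, bowed toward RP and closely positioned; 1, located at a distant position from RP.
16	CuA fused CuPa-alpha: 0, basal half of the wing; 1, distal half of the wing.
17	Cross veins between CuPb and CuPa-beta in the basal part: 0, strongly curved; 1, straight.
18	M forks into MA and MP: 0, basal or at the level of 2/5; 1, at the level of or distal to 1/2 of wing length.
19	M + CuA diverges: 0, closer to one third of the wing length than to the second fifth; 1, closer to the second fifth; 2, closer to the middle of the wing than to the second fifth.
20	Free CuPa-alpha vs free CuA: 0, longer than the free CuA; 1, approximate in length.
21	Basal area between CuPb and CuPa: 0, approximately the same width as the area between CuPa and M + CuA; 1, distinctly narrower.
22	Handle: 0, shorter than the free CuA; 1, same length as the free CuA; 2, distinctly longer than the free CuA.
23	CuPa forked into CuPa-beta and CuPa-alpha: 0, at the level of the fusion of CuPb and AA1; 1, at the level of the bow of AA1 after its fusion with CuPb; 2, distal of the bow of AA1 after its fusion with CuPb.
24	Length of the handle vs length of CuPa-beta between CuPa and handle: 0, shorter; 1, approximately the same length or not longer than twice; 2, longer than twice.
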