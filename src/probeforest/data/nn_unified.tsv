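# Unified nearest-neighbor parameters for DNA/DNA duplexes.
# step notation: 5'-XY-3' top strand / 3'-WZ-5' bottom strand; the
# strand-swapped presentation ZW/YX refers to the same physical step.
# Watson-Crick steps and GC/AT initiation: SantaLucia unified set.
# Single-internal-mismatch and tandem G.T steps: Allawi & SantaLucia
# (G.T, C.T, A.C, A.G series) and Peyret et al. (like-with-like).
# Values for H are in J/mol. Values for S are in J/(K*mol).
# Salt: dG gains salt_coeff * (paired_bases - 1) * ln[Na+], with
# salt_coeff = -0.114 kcal/mol = -476.976 J/mol per phosphate pair
# (the unified dG37 salt dependence); zero at the 1 M default.
step	dH	dS	class
AA/TT	-33053.6	-92.8848	match
AT/TA	-30124.8	-85.3536	match
TA/AT	-30124.8	-89.1192	match
CA/GT	-35564.0	-94.9768	match
GT/CA	-35145.6	-93.7216	match
CT/GA	-32635.2	-87.8640	match
GA/CT	-34308.8	-92.8848	match
CG/GC	-44350.4	-113.8048	match
GC/CG	-41003.2	-102.0896	match
GG/CC	-33472.0	-83.2616	match
AG/TT	4184.0	3.7656	mismatch
AT/TG	-10460.0	-34.7272	mismatch
CG/GT	-17154.4	-48.9528	mismatch
CT/GG	-11715.2	-33.4720	mismatch
GG/CT	13807.2	43.5136	mismatch
GT/CG	-18409.6	-51.4632	mismatch
TG/AT	-418.4	-7.1128	mismatch
TT/AG	-5439.2	-22.1752	mismatch
GG/TT	24267.2	68.1992	mismatch
GT/TG	17154.4	39.7480	mismatch
TG/GT	-5857.6	-25.9408	mismatch
AC/TT	2928.8	0.8368	mismatch
AT/TC	-5020.8	-25.9408	mismatch
CC/GT	-3347.2	-18.8280	mismatch
CT/GC	-6276.0	-25.5224	mismatch
GC/CT	9623.2	22.5936	mismatch
GT/CC	21756.8	56.4840	mismatch
TC/AT	5020.8	2.9288	mismatch
TT/AC	4184.0	2.9288	mismatch
AA/TC	9623.2	19.2464	mismatch
AC/TA	22175.2	61.0864	mismatch
CA/GC	7949.6	15.4808	mismatch
CC/GA	2510.4	-2.5104	mismatch
GA/CC	21756.8	59.4128	mismatch
GC/CA	-2928.8	-15.8992	mismatch
TA/AC	14225.6	33.4720	mismatch
TC/AA	31798.4	84.5168	mismatch
AA/TG	-2510.4	-9.6232	mismatch
AG/TA	-2928.8	-9.6232	mismatch
CA/GG	-2928.8	-9.6232	mismatch
CG/GA	-16736.0	-55.2288	mismatch
GA/CG	-2510.4	-4.1840	mismatch
GG/CA	2092.0	13.3888	mismatch
TA/AG	2928.8	2.9288	mismatch
TG/AA	12552.0	30.9616	mismatch
AA/TA	5020.8	7.1128	mismatch
CA/GA	-3765.6	-17.5728	mismatch
GA/CA	-12133.6	-41.0032	mismatch
TA/AA	19664.8	53.9736	mismatch
AC/TC	0.0	-18.4096	mismatch
CC/GC	-6276.0	-30.1248	mismatch
GC/CC	15062.4	37.2376	mismatch
TC/AC	25522.4	68.6176	mismatch
AG/TG	-12970.4	-39.7480	mismatch
CG/GG	-20501.6	-64.0152	mismatch
GG/CG	-25104.0	-66.1072	mismatch
TG/AG	6694.4	15.0624	mismatch
AT/TT	-11296.8	-45.1872	mismatch
CT/GT	-20920.0	-66.1072	mismatch
GT/CT	-9204.8	-35.1456	mismatch
TT/AT	836.8	-6.2760	mismatch
init_GC	418.4	-11.7152	initiation
init_AT	9623.2	17.1544	initiation
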