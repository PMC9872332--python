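file	fixture	provenance
tml_tin_peaks.tsv	tml_tin_peaks	TML flow-peak whole-chromosome probes hybridised on TIN metaphases, as printed (composite peaks preserved, duplicated NOR peak row preserved)
tml_tin_peak_assignments.tsv	tml_tin_assignments	per-member attribution of composite-peak signals, from the published one-to-one probe enumeration
apk_matrix.tsv	apk_matrix	ancestral Paenungulata homology matrix: 28 ancestral autosomes vs OAF/LAF/TML/PCA/TIN/HSA with inv and inv/cr structural flags
tml_laf_arms.tsv	tml_arm_maps[LAF]	arm-level homologies of TML 4/6/8/9 in the African elephant
tml_pca_arms.tsv	tml_arm_maps[PCA]	arm-level homologies of TML 4/6/8/9 in the hyrax
tml_tin_arms.tsv	tml_arm_maps[TIN]	arm-level homologies of TML 4/6/8/9 in the Amazonian manatee
karyotype_TIN.tsv	karyotype_TIN	Amazonian manatee complement: 2n=56, FN=92, 19 bi-armed + 8 acrocentric autosome pairs
karyotype_TML.tsv	karyotype_TML	Florida manatee complement: 2n=48, FN=92, all 23 autosome pairs bi-armed
karyotype_APK.tsv	karyotype_APK	ancestral Paenungulata complement: 2n=58, morphology unreported
karyotype_LAF.tsv	karyotype_LAF	African elephant complement: 2n=56, morphology unreported
karyotype_PCA.tsv	karyotype_PCA	hyrax complement: 2n=54, morphology unreported
hsa_associations.tsv	hsa_assoc_published	published list of HSA syntenic associations present/absent in TIN
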