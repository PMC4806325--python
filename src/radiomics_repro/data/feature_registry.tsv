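name	class	dim	params
Uni	Size	2D	max axial diameter, mm
Bi	Size	2D	Uni x max perpendicular diameter, mm^2
Volume	Size	3D	voxel count x voxel volume, mm^3
Compactness_3D	Shape	3D	6*sqrt(pi)*V/S^1.5
Roundness_2D	Shape	2D	4*pi*A/P^2 on largest slice
Eccentricity_2D	Shape	2D	second-moment eccentricity on largest slice
Solidity_3D	Shape	3D	V / convex hull volume
ShapeIndex_1	ShapeIndex	3D	bin [-1.000,-0.778)
ShapeIndex_2	ShapeIndex	3D	bin [-0.778,-0.556)
ShapeIndex_3	ShapeIndex	3D	bin [-0.556,-0.333)
ShapeIndex_4	ShapeIndex	3D	bin [-0.333,-0.111)
ShapeIndex_5	ShapeIndex	3D	bin [-0.111,+0.111)
ShapeIndex_6	ShapeIndex	3D	bin [+0.111,+0.333)
ShapeIndex_7	ShapeIndex	3D	bin [+0.333,+0.556)
ShapeIndex_8	ShapeIndex	3D	bin [+0.556,+0.778)
ShapeIndex_9	ShapeIndex	3D	bin [+0.778,+1.000]
Sigmoid_Amplitude	Sigmoid	3D	median boundary-fit amplitude, HU
Sigmoid_Width	Sigmoid	3D	median boundary-fit width, mm
Mean_3D	FirstOrder	3D	mean in-mask HU
SD_3D	FirstOrder	3D	population SD of in-mask HU
Skewness_3D	FirstOrder	3D	m3/m2^1.5
Kurtosis_3D	FirstOrder	3D	m4/m2^2 - 3
Mean_2D	FirstOrder	2D	largest slice
SD_2D	FirstOrder	2D	largest slice
Skewness_2D	FirstOrder	2D	largest slice
Kurtosis_2D	FirstOrder	2D	largest slice
GLCM_Energy	GLCM	2D	angular second moment
GLCM_Entropy	GLCM	2D	bits
GLCM_Contrast	GLCM	2D
GLCM_Dissimilarity	GLCM	2D
GLCM_Homogeneity	GLCM	2D	inverse difference moment
GLCM_Correlation	GLCM	2D
GLCM_Variance	GLCM	2D
GLCM_SumAverage	GLCM	2D
GLCM_SumVariance	GLCM	2D
GLCM_SumEntropy	GLCM	2D	bits
GLCM_DifferenceVariance	GLCM	2D
GLCM_DifferenceEntropy	GLCM	2D	bits
GLCM_IMC1	GLCM	2D	information measure of correlation 1
GLCM_IMC2	GLCM	2D	information measure of correlation 2
GLCM_Autocorrelation	GLCM	2D
GLCM_ClusterShade	GLCM	2D
GLCM_ClusterProminence	GLCM	2D
GTDM_Coarseness	GTDM	2D	Amadasun-King
GTDM_Contrast	GTDM	2D	Amadasun-King
GTDM_Busyness	GTDM	2D	Amadasun-King
GTDM_Complexity	GTDM	2D	Amadasun-King
GTDM_Strength	GTDM	2D	Amadasun-King
AutoCorr_X	SpatialCorrelation	2D	lag-1 Pearson along x
AutoCorr_Y	SpatialCorrelation	2D	lag-1 Pearson along y
RL_SRE	RunLength	2D	short run emphasis
RL_LRE	RunLength	2D	long run emphasis
RL_GLN	RunLength	2D	gray-level nonuniformity
RL_RLN	RunLength	2D	run-length nonuniformity
RL_RP	RunLength	2D	run percentage
RL_LGRE	RunLength	2D	low gray-level run emphasis
RL_HGRE	RunLength	2D	high gray-level run emphasis
RL_SRLGE	RunLength	2D	short run low gray-level emphasis
RL_SRHGE	RunLength	2D	short run high gray-level emphasis
RL_LRLGE	RunLength	2D	long run low gray-level emphasis
RL_LRHGE	RunLength	2D	long run high gray-level emphasis
Laws_L5E5	Laws	2D	mean |response|, L5E5/E5L5 averaged
Laws_L5S5	Laws	2D	mean |response|, L5S5/S5L5 averaged
Laws_E5E5	Laws	2D	mean |response|
Laws_E5S5	Laws	2D	mean |response|, E5S5/S5E5 averaged
Laws_S5S5	Laws	2D	mean |response|
EF_d1	EdgeFrequency	2D	mean |I(p)-I(p+u)| at distance 1
EF_d2	EdgeFrequency	2D	distance 2
EF_d3	EdgeFrequency	2D	distance 3
EF_Coarseness	EdgeFrequency	2D	1/(1 + mean_d EF(d))
Gabor_Energy_0	Gabor	2D	wavelength 4 px, sigma 2 px, 0 deg
Gabor_Energy_90	Gabor	2D	wavelength 4 px, sigma 2 px, 90 deg
Wavelet_L1_LL	Wavelet	2D	Haar level 1 approximation energy
Wavelet_L1_LH	Wavelet	2D	Haar level 1 detail energy
Wavelet_L1_HL	Wavelet	2D	Haar level 1 detail energy
Wavelet_L1_HH	Wavelet	2D	Haar level 1 diagonal energy
Wavelet_L2_LL	Wavelet	2D	Haar level 2 approximation energy
Wavelet_L2_LH	Wavelet	2D	Haar level 2 detail energy
Wavelet_L2_HL	Wavelet	2D	Haar level 2 detail energy
Wavelet_L2_HH	Wavelet	2D	Haar level 2 diagonal energy
LoG_Mean_s1	LoG	2D	s=1, no preprocessing
LoG_Mean_s2	LoG	2D	sigma 0.8333 px
LoG_Mean_s3	LoG	2D	sigma 1.6667 px
LoG_Mean_s4	LoG	2D	sigma 2.5 px
LoG_Uniformity_s1	LoG	2D	sum p^2, 64 bins
LoG_Uniformity_s2	LoG	2D	sum p^2, 64 bins
LoG_Uniformity_s3	LoG	2D	sum p^2, 64 bins
LoG_Uniformity_s4	LoG	2D	sum p^2, 64 bins
FractalDimension_3D	Fractal	3D	surface box counting, eps in {1,2,4,8}
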