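# Published per-case best-threshold deviation statistics: 10 stone-model
# cases x 3 scanning modalities, one row per case with the lowest
# Dissimilarity Index (di = median_mm * iqr_mm * 1000, printed to 1 decimal).
device,threshold_hu,p95_mm,median_mm,iqr_mm,di
Planmeca80,2425,0.18,0.051,0.062,3.2
Planmeca80,2225,0.19,0.057,0.076,4.3
Planmeca80,2325,0.19,0.055,0.073,4.0
Planmeca80,2125,0.19,0.065,0.078,5.1
Planmeca80,2025,0.17,0.053,0.063,3.3
Planmeca80,2325,0.15,0.053,0.068,3.6
Planmeca80,1925,0.20,0.069,0.082,5.7
Planmeca80,2225,0.16,0.056,0.070,3.9
Planmeca80,2025,0.18,0.067,0.080,5.3
Planmeca80,1925,0.21,0.060,0.080,4.8
Planmeca90,2425,0.20,0.051,0.061,3.1
Planmeca90,2325,0.18,0.050,0.080,4.0
Planmeca90,2225,0.16,0.057,0.073,4.1
Planmeca90,2225,0.19,0.052,0.070,3.6
Planmeca90,2125,0.20,0.063,0.084,5.3
Planmeca90,2325,0.17,0.053,0.063,3.3
Planmeca90,2025,0.16,0.057,0.076,4.3
Planmeca90,2025,0.19,0.063,0.078,4.9
Planmeca90,1925,0.18,0.070,0.080,5.6
Planmeca90,1825,0.21,0.058,0.078,4.5
NewtomVG,2225,0.13,0.045,0.063,2.8
NewtomVG,2025,0.12,0.035,0.049,1.7
NewtomVG,1925,0.13,0.043,0.053,2.3
NewtomVG,2025,0.13,0.039,0.049,1.9
NewtomVG,1825,0.14,0.044,0.058,2.5
NewtomVG,2125,0.10,0.032,0.039,1.2
NewtomVG,2025,0.11,0.032,0.047,1.5
NewtomVG,1925,0.13,0.035,0.052,1.8
NewtomVG,1825,0.16,0.049,0.065,3.2
NewtomVG,1825,0.16,0.045,0.051,2.3
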