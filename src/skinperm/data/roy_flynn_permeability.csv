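experiment,individual_id,site,preparation,vehicle_pH,compound,n_replicates,P_mean_1e6_cm_s,P_sd_1e6_cm_s
F01,D01,thigh,heat-separated,7.40,fentanyl,4,2.83,0.28
F02,D02,thigh,heat-separated,7.40,fentanyl,4,2.61,0.47
F03,D03,thigh,heat-separated,7.40,fentanyl,4,4.86,0.42
F04,D04,abdomen,heat-separated,7.40,fentanyl,4,1.53,0.25
F05,D05,thigh,heat-separated,7.40,fentanyl,4,4.47,0.17
F06,D06,abdomen,heat-separated,7.40,fentanyl,5,3.78,0.72
F07,D07,thigh,heat-separated,7.40,fentanyl,5,0.83,0.31
F08,D08,abdomen,heat-separated,7.40,fentanyl,4,3.25,0.33
F09,D09,abdomen,heat-separated,7.40,fentanyl,5,4.22,0.50
F10,D10,abdomen,heat-separated,7.40,fentanyl,5,3.86,0.94
F11,D11,abdomen,heat-separated,7.40,fentanyl,4,2.22,0.53
S01,D01,thigh,heat-separated,7.40,sufentanil,4,4.36,0.25
S02,D02,thigh,heat-separated,7.40,sufentanil,4,4.33,0.53
S03,D03,thigh,heat-separated,7.40,sufentanil,4,5.81,0.39
S04,D04,abdomen,heat-separated,7.40,sufentanil,4,3.44,0.31
S05,D05,thigh,heat-separated,7.40,sufentanil,4,6.47,0.33
S06,D06,abdomen,heat-separated,7.40,sufentanil,5,4.22,0.81
S07,D07,thigh,heat-separated,7.40,sufentanil,5,1.53,0.42
S08,D08,abdomen,heat-separated,7.40,sufentanil,4,4.83,0.50
S09,D09,abdomen,heat-separated,7.40,sufentanil,5,4.61,0.47
S10,D10,abdomen,heat-separated,7.40,sufentanil,5,4.53,1.06
S11,D11,abdomen,heat-separated,7.40,sufentanil,4,2.33,0.47
FpH1,D12,thigh,dermatomed,2.88,fentanyl,4,0.08,0.01
FpH2,D12,thigh,dermatomed,5.08,fentanyl,4,0.36,0.08
FpH3,D12,thigh,dermatomed,6.02,fentanyl,4,1.42,0.22
FpH4,D12,thigh,dermatomed,6.95,fentanyl,4,1.97,0.19
FpH5,D12,thigh,dermatomed,7.43,fentanyl,4,3.53,0.83
FpH6,D12,thigh,dermatomed,7.95,fentanyl,4,6.22,0.47
FpH7,D12,thigh,dermatomed,8.52,fentanyl,4,7.67,0.64
FpH8,D12,thigh,dermatomed,9.04,fentanyl,4,9.69,1.75
FpH9,D12,thigh,dermatomed,9.37,fentanyl,4,9.14,1.75
SpH1,D12,thigh,dermatomed,2.88,sufentanil,4,0.13,0.01
SpH2,D12,thigh,dermatomed,5.08,sufentanil,4,0.69,0.03
SpH3,D12,thigh,dermatomed,6.02,sufentanil,4,1.72,0.31
SpH4,D12,thigh,dermatomed,6.95,sufentanil,4,2.81,0.17
SpH5,D12,thigh,dermatomed,7.43,sufentanil,4,4.36,0.22
SpH6,D12,thigh,dermatomed,7.95,sufentanil,4,6.42,0.44
SpH7,D12,thigh,dermatomed,8.52,sufentanil,4,8.28,1.03
SpH8,D12,thigh,dermatomed,9.04,sufentanil,4,9.58,0.69
SpH9,D12,thigh,dermatomed,9.37,sufentanil,4,9.36,1.86
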