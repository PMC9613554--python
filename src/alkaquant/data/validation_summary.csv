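analyte_id,recovery_pct_0p05,rsd_r_pct_0p05,recovery_pct_0p50,rsd_r_pct_0p50,recovery_pct_3p00,rsd_r_pct_3p00,lod_ugL,loq_ugL,r_squared,linear_up_to_ugL,matrix_suppression_pct
AcIm,94.0,5.0,95.0,6.7,85.7,2.3,0.007,0.009,0.9984,3.7,35.1
AcLy,92.3,4.2,95.6,6.5,82.7,3.1,0.007,0.02,0.9992,3.7,33.0
At,87.0,6.5,96.2,7.8,92.9,2.2,0.01,0.021,0.9926,5.5,37.7
Ec,106.4,7.8,102.5,5.6,95.1,3.6,0.009,0.009,0.9958,5.5,52.9
EcN,104.3,7.2,97.0,2.7,85.0,3.5,0.012,0.036,0.9972,5.5,52.5
Em,103.3,3.4,102.1,7.6,87.4,2.9,0.011,0.026,0.9992,3.7,43.1
EmN,99.2,5.1,98.4,5.9,90.1,4.5,0.008,0.018,0.9992,3.7,33.6
En,114.4,3.2,100.2,4.3,91.3,2.3,0.007,0.019,0.9996,3.7,38.0
EnN/RrN,102.6,7.7,102.9,7.7,90.1,4.7,0.019,0.033,0.9982,5.5,50.9
Eu,105.1,3.3,102.6,7.2,92.4,3.7,0.007,0.021,0.996,3.7,24.3
EuN,107.5,6.1,102.6,5.6,90.7,3.6,0.008,0.025,0.9988,5.5,35.6
Hs,122.1,4.5,106.3,3.4,94.4,1.6,0.01,0.026,0.9978,5.5,39.2
HsN,97.9,7.3,104.4,3.4,96.6,3.1,0.008,0.023,0.9946,5.5,40.0
Ht,102.9,2.8,101.4,5.8,90.4,3.5,0.007,0.021,0.998,2.8,35.3
HtN,107.5,2.2,100.4,4.5,91.6,3.2,0.009,0.012,0.9986,5.5,25.9
Ic/Im,104.8,5.9,102.0,7.0,95.7,2.5,0.007,0.019,0.998,5.5,23.3
IcN/LyN,105.9,6.0,97.2,5.7,88.2,1.5,0.015,0.03,0.9994,3.7,27.2
Ig,97.1,6.8,94.4,2.8,94.6,3.9,0.012,0.03,0.996,5.5,61.5
IgN,113.4,6.1,104.9,6.5,96.3,4.3,0.022,0.027,0.998,5.5,33.1
ImN,114.1,7.7,102.0,5.9,92.6,3.5,0.006,0.015,0.9996,5.5,33.8
Jb,107.3,4.0,127.0,5.7,114.2,2.5,0.017,0.039,0.9984,3.7,58.3
JbN,107.8,3.7,98.1,3.4,90.0,1.6,0.007,0.019,0.999,5.5,39.1
Jl,,,97.1,5.9,91.0,2.4,0.023,0.056,0.9984,5.5,40.4
JlN,111.4,6.0,97.1,5.0,87.2,3.1,0.011,0.022,0.9982,5.5,43.3
Jn,65.1,7.4,67.7,9.1,64.4,2.0,0.023,0.036,0.9962,5.5,44.4
Lc,92.9,9.8,108.6,12.3,79.0,1.3,0.015,0.043,0.994,5.5,74.0
LcN,108.3,5.2,108.4,5.8,94.9,2.7,0.01,0.021,0.9988,5.5,25.5
Ly,111.7,6.4,105.8,7.3,97.0,3.7,0.01,0.016,0.998,5.5,25.6
Mc,96.8,4.3,97.4,7.1,92.7,1.4,0.013,0.04,0.9986,5.5,34.3
McN,98.6,1.6,92.3,5.3,84.3,4.1,0.01,0.016,0.9958,5.5,48.0
Mk,69.0,13.1,79.2,7.9,74.8,2.6,0.02,0.044,0.9992,5.5,41.8
MkN,,,12.5,27.3,13.4,14.6,0.013,0.101,0.9986,5.5,29.3
Mx,,,121.0,4.6,103.4,3.2,0.039,0.123,0.9974,5.5,57.7
MxN,175.6,5.8,172.2,3.6,156.9,6.3,0.012,0.037,0.9952,5.5,41.5
Rl,92.1,13.4,81.3,5.5,76.4,2.4,0.011,0.038,0.9982,5.5,56.0
RlN,35.5,8.8,32.5,6.5,36.2,2.8,0.01,0.025,0.9986,5.5,24.3
Rr,103.3,2.0,98.9,3.8,91.7,3.2,0.005,0.014,0.999,3.7,43.8
Rs,100.5,6.8,99.4,6.3,90.8,2.0,0.012,0.039,0.9976,5.5,48.9
RsN,103.1,9.9,99.6,7.8,90.3,1.7,0.013,0.016,0.9992,5.5,34.5
Sc,103.6,3.6,96.3,4.5,89.5,2.4,0.008,0.015,0.9934,5.5,52.9
ScN,116.9,12.5,99.8,7.1,92.8,7.2,0.017,0.039,0.9984,3.7,32.4
Sco,105.3,6.1,102.1,4.2,92.7,3.7,0.009,0.027,0.998,5.5,41.3
Sd,92.6,12.2,88.8,6.6,80.3,2.9,0.04,0.04,0.999,5.5,44.2
Sk,93.0,9.8,99.4,3.2,93.5,2.9,0.011,0.034,0.9998,3.7,41.7
Sl,,,96.8,5.3,91.1,2.2,0.054,0.054,0.9986,5.5,39.5
SlN,114.3,1.9,101.1,3.7,92.6,2.6,0.047,0.047,0.9986,5.5,38.8
Sp,103.1,3.2,95.2,5.5,84.8,3.4,0.011,0.032,0.9968,5.5,49.0
SpN,68.4,7.9,65.1,8.2,65.5,4.2,0.032,0.032,0.9988,5.5,27.8
Sv,103.3,6.9,98.2,3.0,91.6,3.1,0.009,0.019,0.996,5.5,57.2
SvN,95.2,12.3,102.0,6.0,95.4,4.0,0.022,0.022,0.9988,5.5,44.0
Td,103.4,8.8,100.6,5.4,92.2,1.9,0.041,0.041,0.9972,5.5,43.9
Us,104.3,9.4,100.9,7.7,91.1,3.3,0.011,0.034,0.997,5.5,42.1
UsN,99.3,6.9,97.7,7.0,86.4,3.8,0.009,0.028,0.9992,3.7,46.6
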