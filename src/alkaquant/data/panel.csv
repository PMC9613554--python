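analyte_id,analyte_name,role,expected_rt_min,precursor_mz,product_mz,dp_v,ce_v,cxp_v,expected_ion_ratio
McN,Monocrotaline-N-oxide,quantifier,3.9,342.2,137.1,116,41,24,
McN,Monocrotaline-N-oxide,qualifier,3.9,342.2,118.1,116,67,22,0.38
JlN,Jacoline-N-oxide,quantifier,3.9,386.3,120.1,111,59,22,
JlN,Jacoline-N-oxide,qualifier,3.9,386.3,172.1,111,51,30,0.39
SlN,Sceleratine-N-oxide,quantifier,4.2,386.3,118.1,121,51,22,
SlN,Sceleratine-N-oxide,qualifier,4.2,386.3,340.2,121,41,20,0.37
ImN,Intermedine-N-oxide,quantifier,4.8,316.2,172.0,96,39,32,
ImN,Intermedine-N-oxide,qualifier,4.8,316.2,94.1,96,59,16,0.64
IcN,Indicine-N-oxide,quantifier,5.0,316.2,172.1,101,39,30,
IcN,Indicine-N-oxide,qualifier,5.0,316.2,94.1,101,61,16,0.64
LyN,Lycopsamine-N-oxide,quantifier,5.0,316.2,172.1,86,39,30,
LyN,Lycopsamine-N-oxide,qualifier,5.0,316.2,138.1,86,39,24,0.66
EcN,Erucifoline-N-oxide,quantifier,5.1,366.2,118.0,106,47,20,
EcN,Erucifoline-N-oxide,qualifier,5.1,366.2,136.0,106,45,24,0.85
EuN,Europine-N-oxide,quantifier,5.2,346.2,172.0,91,45,30,
EuN,Europine-N-oxide,qualifier,5.2,346.2,270.1,91,35,14,0.26
EnN,Echinatine-N-oxide,quantifier,5.5,316.2,172.1,101,41,10,
EnN,Echinatine-N-oxide,qualifier,5.5,316.2,80.0,101,83,14,0.4
RrN,Rinderine-N-oxide,quantifier,5.5,316.2,172.3,76,41,10,
RrN,Rinderine-N-oxide,qualifier,5.5,316.2,80.0,76,89,14,0.41
JbN,Jacobine-N-oxide,quantifier,6.4,368.2,296.2,101,35,16,
JbN,Jacobine-N-oxide,qualifier,6.4,368.2,120.1,101,53,22,0.76
RlN,Riddelliine-N-oxide,quantifier,6.5,366.1,93.8,96,65,10,
RlN,Riddelliine-N-oxide,qualifier,6.5,366.1,118.2,96,51,6,0.7
MxN,Merepoxine-N-oxide,quantifier,7.4,368.2,136.0,121,45,24,
MxN,Merepoxine-N-oxide,qualifier,7.4,368.2,120.1,121,55,22,0.2
MkN,Merenskine-N-oxide,quantifier,7.4,404.1,118.1,71,61,20,
MkN,Merenskine-N-oxide,qualifier,7.4,404.1,138.1,71,53,26,0.53
UsN,Usaramine-N-oxide,quantifier,8.0,368.1,118.3,101,47,6,
UsN,Usaramine-N-oxide,qualifier,8.0,368.1,94.1,101,67,16,1.81
HtN,Heliotrine-N-oxide,quantifier,8.2,330.2,172.2,96,39,30,
HtN,Heliotrine-N-oxide,qualifier,8.2,330.2,111.0,96,59,20,0.35
RsN,Retrorsine-N-oxide,quantifier,8.2,368.2,118.0,111,43,20,
RsN,Retrorsine-N-oxide,qualifier,8.2,368.2,340.2,111,39,20,0.23
Jl,Jacoline,quantifier,8.3,370.2,120.1,111,47,22,
Jl,Jacoline,qualifier,8.3,370.2,326.2,111,37,18,0.41
Im,Intermedine,quantifier,8.5,300.1,94.0,91,39,16,
Im,Intermedine,qualifier,8.5,300.1,138.0,91,29,24,1.18
Ic,Indicine,quantifier,8.5,300.2,138.0,91,29,24,
Ic,Indicine,qualifier,8.5,300.2,156.1,91,41,28,0.71
Ly,Lycopsamine,quantifier,8.7,300.2,94.0,101,39,16,
Ly,Lycopsamine,qualifier,8.7,300.2,138.1,101,29,24,0.7
Mc,Monocrotaline,quantifier,8.9,326.2,120.1,106,51,22,
Mc,Monocrotaline,qualifier,8.9,326.2,237.2,106,35,12,0.37
SpN,Seneciphylline-N-oxide,quantifier,9.2,350.2,94.1,96,67,16,
SpN,Seneciphylline-N-oxide,qualifier,9.2,350.2,322.3,96,35,18,0.18
Sl,Sceleratine,quantifier,9.2,370.2,138.1,116,43,24,
Sl,Sceleratine,qualifier,9.2,370.2,342.2,116,39,18,0.23
AcImN,7-O-Acetylintermedine-N-oxide,quantifier,9.5,358.2,214.1,91,39,38,
AcImN,7-O-Acetylintermedine-N-oxide,qualifier,9.5,358.2,180.1,91,41,32,0.54
AcLyN,7-O-Acetyllycopsamine-N-oxide,quantifier,9.6,358.2,214.1,96,39,38,
AcLyN,7-O-Acetyllycopsamine-N-oxide,qualifier,9.6,358.2,180.1,96,41,32,0.64
Eu,Europine,quantifier,10.6,330.2,138.1,86,33,24,
Eu,Europine,qualifier,10.6,330.2,254.1,86,27,14,0.37
IgN,Integerrimine-N-oxide,quantifier,10.9,352.2,118.0,101,43,20,
IgN,Integerrimine-N-oxide,qualifier,10.9,352.2,136.0,101,47,24,0.75
ScN,Senecionine-N-oxide,quantifier,11.2,352.1,118.0,106,45,20,
ScN,Senecionine-N-oxide,qualifier,11.2,352.1,324.2,106,37,18,0.22
En,Echinatine,quantifier,11.2,300.1,138.2,81,31,8,
En,Echinatine,qualifier,11.2,300.1,94.1,81,57,16,0.29
SvN,Senecivernine-N-oxide,quantifier,11.3,352.2,118.1,96,45,22,
SvN,Senecivernine-N-oxide,qualifier,11.3,352.2,324.3,96,37,18,0.34
Rr,Rinderine,quantifier,11.4,300.1,138.0,76,31,8,
Rr,Rinderine,qualifier,11.4,300.1,156.0,76,39,8,0.45
Sk,Senkirkine,quantifier,11.6,366.3,168.2,96,43,8,
Sk,Senkirkine,qualifier,11.6,366.3,150.1,96,39,26,0.41
HsN,Heliosupine-N-oxide,quantifier,12.6,414.3,94.1,81,65,18,
HsN,Heliosupine-N-oxide,qualifier,12.6,414.3,118.1,81,85,22,0.64
Ec,Erucifoline,quantifier,13.2,350.2,120.0,96,41,22,
Ec,Erucifoline,qualifier,13.2,350.2,138.1,96,41,24,0.67
EmN,Echimidine-N-oxide,quantifier,13.2,414.3,254.3,91,43,14,
EmN,Echimidine-N-oxide,qualifier,13.2,414.3,352.2,91,35,20,0.36
Jb,Jacobine,quantifier,13.7,352.2,120.0,111,43,20,
Jb,Jacobine,qualifier,13.7,352.2,280.2,111,33,16,0.96
Rl,Riddelliine,quantifier,14.0,350.1,120.1,101,39,22,
Rl,Riddelliine,qualifier,14.0,350.1,94.1,101,59,18,0.61
Ht,Heliotrine,quantifier,14.5,314.2,138.0,76,29,24,
Ht,Heliotrine,qualifier,14.5,314.2,156.1,76,39,28,0.29
Mx,Merepoxine,quantifier,14.8,352.1,120.1,141,45,22,
Mx,Merepoxine,qualifier,14.8,352.1,324.2,141,39,32,0.4
LcN,Lasiocarpine-N-oxide,quantifier,15.1,428.3,254.1,91,41,14,
LcN,Lasiocarpine-N-oxide,qualifier,15.1,428.3,352.3,91,35,20,0.6
Us,Usaramine,quantifier,15.1,352.1,120.1,106,43,6,
Us,Usaramine,qualifier,15.1,352.1,94.1,106,57,16,0.5
At,Atropine,quantifier,15.1,290.2,124.1,86,35,6,
At,Atropine,qualifier,15.1,290.2,93.1,86,43,16,0.5
Rs,Retrorsine,quantifier,15.5,352.2,120.1,101,43,20,
Rs,Retrorsine,qualifier,15.5,352.2,324.2,101,39,18,0.68
Td,Trichodesmine,quantifier,15.6,354.2,222.2,86,41,12,
Td,Trichodesmine,qualifier,15.6,354.2,308.2,86,30,15,0.13
Sco,Scopolamine,quantifier,15.6,304.1,138.1,71,35,8,
Sco,Scopolamine,qualifier,15.6,304.1,156.1,71,23,8,0.51
Jn,Jaconine,quantifier,15.9,388.1,94.2,111,61,18,
Jn,Jaconine,qualifier,15.9,388.1,156.2,111,55,8,0.74
AcIm,7-O-Acetylintermedine,quantifier,16.1,342.2,120.0,81,37,22,
AcIm,7-O-Acetylintermedine,qualifier,16.1,342.2,180.1,81,25,32,0.35
AcLy,7-O-Acetyllycopsamine,quantifier,16.3,342.2,120.0,81,35,22,
AcLy,7-O-Acetyllycopsamine,qualifier,16.3,342.2,180.1,81,25,32,0.22
Sd,Spartioidine,quantifier,16.4,334.1,119.9,101,39,6,
Sd,Spartioidine,qualifier,16.4,334.1,94.1,101,53,18,0.6
Mk,Merenskine,quantifier,16.5,388.2,120.0,121,51,22,
Mk,Merenskine,qualifier,16.5,388.2,138.0,121,45,24,0.86
Sp,Seneciphylline,quantifier,16.9,334.2,120.1,111,39,22,
Sp,Seneciphylline,qualifier,16.9,334.2,306.2,111,35,18,0.71
Ig,Integerrimine,quantifier,18.3,336.3,120.1,96,41,22,
Ig,Integerrimine,qualifier,18.3,336.3,308.2,96,37,18,0.47
Sc,Senecionine,quantifier,18.8,336.3,120.1,106,41,22,
Sc,Senecionine,qualifier,18.8,336.3,308.2,106,37,18,0.57
Sv,Senecivernine,quantifier,19.3,336.2,120.1,96,43,22,
Sv,Senecivernine,qualifier,19.3,336.2,308.2,96,39,18,0.76
Hs,Heliosupine,quantifier,19.3,398.2,119.8,81,39,6,
Hs,Heliosupine,qualifier,19.3,398.2,220.3,81,27,12,0.53
Em,Echimidine,quantifier,19.8,398.3,120.0,76,35,22,
Em,Echimidine,qualifier,19.8,398.3,220.1,76,25,12,0.31
Lc,Lasiocarpine,quantifier,22.4,412.3,120.0,86,39,22,
Lc,Lasiocarpine,qualifier,22.4,412.3,220.2,86,27,12,0.44
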