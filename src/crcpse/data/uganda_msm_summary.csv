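town,population,adult_population,objects_offered,refusals,n_capture1,n_capture2,recaptures_def1,recaptures_def2,misidentified,distributor_recaptures
Mbale,MSM,123201,129,28,101,143,46,38,13,d1:6;d2:32
Jinja,MSM,18233,81,0,81,95,17,7,0,d1:5;d2:2
Wakiso,MSM,15228,81,2,79,149,62,32,0,d1:21;d2:11
Mbarara,MSM,48754,99,0,99,120,51,37,10,d1:17;d2:20
Gulu,MSM,38069,109,7,102,153,88,87,5,d1:19;d2:68
Kabarole,MSM,13569,92,8,83,133,61,33,8,d1:26;d2:7
Mukono,MSM,40686,106,2,104,142,88,56,0,d1:36;d2:20
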