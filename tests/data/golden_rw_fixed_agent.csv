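participant_id,trial,block,offer,choice,rating,norm_at_trial
golden,1,baseline,7,reject,,10.0
golden,2,baseline,8,accept,,9.52
golden,3,baseline,7,accept,,9.2768
golden,4,baseline,7,accept,,8.912512
golden,5,baseline,8,accept,,8.60651008
golden,6,baseline,10,accept,,8.5094684672
golden,7,baseline,8,accept,,8.747953512448
golden,8,baseline,6,reject,,8.62828095045632
golden,9,baseline,6,reject,,8.207755998383309
golden,10,baseline,9,accept,,7.8545150386419795
golden,11,baseline,7,accept,,8.037792632459263
golden,12,baseline,7,accept,,7.871745811265781
golden,13,baseline,8,accept,,7.732266481463256
golden,14,baseline,7,accept,,7.775103844429135
golden,15,baseline,6,accept,,7.651087229320473
golden,16,baseline,10,accept,,7.386913272629197
golden,17,baseline,8,accept,,7.805007149008525
golden,18,baseline,10,accept,,7.836206005167162
golden,19,baseline,10,accept,,8.182413044340416
golden,20,baseline,7,accept,,8.47322695724595
golden,21,conditioning,5,reject,,8.237510644086598
golden,22,conditioning,5,reject,,7.719508941032742
golden,23,conditioning,4,reject,,7.2843875104675035
golden,24,conditioning,5,accept,,6.758885508792703
golden,25,conditioning,6,accept,,6.477463827385871
golden,26,conditioning,3,reject,,6.401069615004132
golden,27,conditioning,4,reject,,5.856898476603471
golden,28,conditioning,4,accept,,5.559794720346916
golden,29,conditioning,4,accept,,5.3102275650914095
golden,30,conditioning,3,reject,,5.100591154676784
golden,31,conditioning,3,reject,,4.7644965699284985
golden,32,conditioning,5,accept,,4.482177118739939
golden,33,conditioning,6,accept,,4.5650287797415485
golden,34,conditioning,1,reject,,4.794624174982901
golden,35,conditioning,4,accept,,4.1874843069856365
golden,36,conditioning,4,accept,,4.157486817867935
golden,37,conditioning,4,accept,,4.132288927009065
golden,38,conditioning,1,reject,,4.111122698687614
golden,39,conditioning,6,accept,,3.613343066897596
golden,40,conditioning,7,accept,,3.9952081761939806
golden,41,post,7,accept,,4.475974868002944
golden,42,post,8,accept,,4.879818889122473
golden,43,post,7,accept,,5.379047866862877
golden,44,post,6,accept,,5.638400208164817
golden,45,post,8,accept,,5.696256174858446
golden,46,post,8,accept,,6.064855186881094
golden,47,post,11,accept,,6.374478356980119
golden,48,post,10,accept,,7.1145618198633
golden,49,post,9,accept,,7.576231928685172
golden,50,post,7,accept,,7.804034820095545
golden,51,post,7,accept,,7.675389248880258
golden,52,post,7,accept,,7.567326969059416
golden,53,post,7,accept,,7.4765546540099095
golden,54,post,8,accept,,7.400305909368324
golden,55,post,6,accept,,7.496256963869392
golden,56,post,9,accept,,7.2568558496502895
golden,57,post,8,accept,,7.5357589137062435
golden,58,post,5,reject,,7.610037487513244
golden,59,post,6,accept,,7.192431489511125
golden,60,post,8,accept,,7.001642451189345
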