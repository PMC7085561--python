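test_code,age_band,mean,sd
chair_stand,60-69,14.0,2.4
chair_stand,70-79,12.9,3.0
chair_stand,80-89,11.9,3.6
arm_curl,60-69,19.8,4.1
arm_curl,70-79,18.2,3.9
arm_curl,80-89,16.5,4.1
two_min_step,60-69,100.4,9.0
two_min_step,70-79,92.6,16.0
two_min_step,80-89,83.5,22.6
sit_reach,60-69,-1,14
sit_reach,70-79,-1,15
sit_reach,80-89,-8,15
back_scratch,60-69,3.0,5.0
back_scratch,70-79,-1,8
back_scratch,80-89,-5,11
up_and_go,60-69,5.2,0.6
up_and_go,70-79,6.1,1.2
up_and_go,80-89,7.1,2.0
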