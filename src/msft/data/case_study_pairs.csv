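subject_id,test_code,method,value
1,chair_stand,sft,14
2,chair_stand,sft,15
3,chair_stand,sft,12
4,chair_stand,sft,14
5,chair_stand,sft,10
6,chair_stand,sft,16
7,chair_stand,sft,12
1,chair_stand,msft,12
2,chair_stand,msft,13
3,chair_stand,msft,12
4,chair_stand,msft,13
5,chair_stand,msft,8
6,chair_stand,msft,13
7,chair_stand,msft,9
1,arm_curl,sft,23
2,arm_curl,sft,16
3,arm_curl,sft,15
4,arm_curl,sft,20
5,arm_curl,sft,14
6,arm_curl,sft,16
7,arm_curl,sft,15
1,arm_curl,msft,22
2,arm_curl,msft,15
3,arm_curl,msft,15
4,arm_curl,msft,20
5,arm_curl,msft,14
6,arm_curl,msft,15
7,arm_curl,msft,13
1,two_min_step,sft,75
2,two_min_step,sft,80
3,two_min_step,sft,93
4,two_min_step,sft,97
5,two_min_step,sft,72
6,two_min_step,sft,74
7,two_min_step,sft,85
1,two_min_step,msft,69
2,two_min_step,msft,76
3,two_min_step,msft,83
4,two_min_step,msft,87
5,two_min_step,msft,66
6,two_min_step,msft,67
7,two_min_step,msft,78
1,sit_reach,sft,-1
2,sit_reach,sft,3
3,sit_reach,sft,5
4,sit_reach,sft,-3
5,sit_reach,sft,2.5
6,sit_reach,sft,2
7,sit_reach,sft,-2
1,sit_reach,msft,-1
2,sit_reach,msft,3.5
3,sit_reach,msft,5
4,sit_reach,msft,-2.5
5,sit_reach,msft,3
6,sit_reach,msft,2
7,sit_reach,msft,-2
1,back_scratch,sft,-3.5
2,back_scratch,sft,1
3,back_scratch,sft,2
4,back_scratch,sft,-2.5
5,back_scratch,sft,2.5
6,back_scratch,sft,-1
7,back_scratch,sft,-4
1,back_scratch,msft,-3
2,back_scratch,msft,1.5
3,back_scratch,msft,2.5
4,back_scratch,msft,-2
5,back_scratch,msft,2.5
6,back_scratch,msft,-1
7,back_scratch,msft,-3.5
1,up_and_go,sft,5.3
2,up_and_go,sft,6.2
3,up_and_go,sft,3.5
4,up_and_go,sft,4.1
5,up_and_go,sft,6.1
6,up_and_go,sft,3.3
7,up_and_go,sft,6
1,up_and_go,msft,5
2,up_and_go,msft,6.4
3,up_and_go,msft,3.6
4,up_and_go,msft,4.5
5,up_and_go,msft,5.4
6,up_and_go,msft,3.5
7,up_and_go,msft,6.2
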