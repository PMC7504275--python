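tg,RRO,OO,OO_in_RRO_1.0,OO_in_RRO_2.5,OO_in_RRO_5.0,OO_in_RRO_10.0,RRO_in_OO_1.0,RRO_in_OO_2.5,RRO_in_OO_5.0,RRO_in_OO_10.0
PPO,Nd,20.8,0.8,3.9,4.3,7.9,18.4,17.0,15.0,12.4
PPL,Nd,9.3,0.9,1.9,2.1,2.7,8.5,8.4,8.1,7.4
PSO,Nd,6.7,0.2,1.4,1.9,5.8,7.6,6.0,4.1,3.9
OOP,47.4,254.2,71.5,82.4,105.7,124.7,246.5,235.0,212.0,190.9
POL,53.3,60.6,48.3,50.1,54.2,42.4,55.2,49.0,43.3,43.7
POLn,26.9,1.6,26.1,24.3,23.0,18.9,2.8,4.9,6.4,11.7
OOS,13.7,33.3,11.7,14.5,20.2,23.3,33.2,31.7,29.7,22.5
OOO,424.1,516.5,429.3,430.2,443.8,470.0,515.6,507.8,504.9,500.2
OOL,194.6,88.5,183.3,155.4,137.7,121.5,83.6,91.0,107.6,114.3
OOLn,117.8,Nd,116.8,97.3,80.8,68.2,2.2,4.1,6.0,12.2
LLO,34.9,8.4,32.6,30.7,28.3,24.9,8.7,9.4,9.9,12.7
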