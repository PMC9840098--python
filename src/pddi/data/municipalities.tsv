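# address stems: prefecture+municipality+district used to synthesize addresses
# stem
東京都新宿区西新宿
東京都世田谷区経堂
東京都八王子市元本郷町
神奈川県横浜市中区本町
神奈川県川崎市中原区小杉町
神奈川県藤沢市鵠沼海岸
大阪府大阪市北区中之島
大阪府吹田市山田東
京都府京都市左京区田中里ノ前町
兵庫県神戸市中央区元町通
愛知県名古屋市中村区名駅
愛知県豊田市若宮町
福岡県福岡市博多区博多駅前
北海道札幌市中央区大通西
宮城県仙台市青葉区一番町
広島県広島市中区大手町
岡山県岡山市北区丸の内
石川県金沢市広坂
新潟県新潟市中央区学校町通
熊本県熊本市中央区水前寺
長野県松本市大手
山口県宇部市常盤町
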